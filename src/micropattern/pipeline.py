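"""End-to-end orchestration: images → nuclei → colonies → profiles → stats.

``run_pipeline`` executes the stages in a fixed order for every well and
assembles tidy tables that downstream analysis scripts and the CLI write to
CSV. All stages are deterministic given the inputs, so a rerun reproduces
the output tables byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .colonies import Colony, QCThresholds, colony_table, identify_colonies, qc_filter
from .io import PlateLayout
from .profiling import (BinGeometry, DEFAULT_BINS, PositivityModel, aggregate,
                        assign_bins, colony_profile, estimate_background,
                        normalize_nucleus, percent_positive, well_normalize)
from .segmentation import SegmentationParams, WellImage, detect_nuclei, measure_intensities
from .stats import (ALPHA_MEAN_OUTLIER, ALPHA_RADIAL_OUTLIER, kruskal_dunn,
                    marker_correlations, outlier_mean_expression, outlier_radial,
                    pca_lines)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "process_well"]


@dataclass
class PipelineConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    bins: BinGeometry = field(default_factory=BinGeometry)
    colony_smooth_sigma_um: float = 40.0
    min_nuclei_background: int = 50


@dataclass
class PipelineResult:
    """Tidy output tables plus a run log (versions, thresholds, tallies)."""

    nuclei: pd.DataFrame
    colonies: pd.DataFrame
    profiles: pd.DataFrame          # long: line, experiment, well, colony, marker, bin, value, n
    percent_positive: pd.DataFrame  # one row per qualified colony and marker
    line_profiles: pd.DataFrame     # hierarchical line-level mean/SD per bin
    stats: pd.DataFrame
    correlations: pd.DataFrame
    pca_scores: pd.DataFrame
    log: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nuclei.to_csv(outdir / "nuclei.csv", index=False)
        self.colonies.to_csv(outdir / "colonies.csv", index=False)
        self.profiles.to_csv(outdir / "radial_profiles.csv", index=False)
        self.percent_positive.to_csv(outdir / "percent_positive.csv", index=False)
        self.line_profiles.to_csv(outdir / "line_profiles.csv", index=False)
        self.stats.to_csv(outdir / "stats.csv", index=False)
        self.correlations.to_csv(outdir / "marker_correlations.csv")
        self.pca_scores.to_csv(outdir / "pca_scores.csv")
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, default=str)


def process_well(image: WellImage, cfg: PipelineConfig) -> tuple[pd.DataFrame, list[Colony], dict]:
    """Segment, measure and QC one well; returns nuclei table, colonies, tallies.

    The nuclei table gains colony assignment, radial distance, ring index
    and per-marker DAPI-normalised ratios for nuclei in qualified colonies.
    """
    seg = detect_nuclei(image, cfg.segmentation)
    nuclei = measure_intensities(image, seg)
    seg.table = nuclei
    colonies, _, nuclei = identify_colonies(seg, image, cfg.colony_smooth_sigma_um)
    colonies = qc_filter(colonies, cfg.qc)
    qualified = {c.colony_id for c in colonies if c.qc_status == "qualified"}
    centroids = {c.colony_id: (c.centroid_x_um, c.centroid_y_um) for c in colonies}

    nuclei = nuclei.copy()
    nuclei["well"] = image.well_id
    nuclei["qualified_colony"] = nuclei["colony_id"].isin(qualified)
    d = np.full(len(nuclei), np.nan)
    for cid, (cx, cy) in centroids.items():
        sel = (nuclei["colony_id"] == cid).to_numpy()
        d[sel] = np.hypot(nuclei.loc[sel, "x_um"] - cx, nuclei.loc[sel, "y_um"] - cy)
    nuclei["distance_um"] = d
    bins = np.zeros(len(nuclei), dtype=int)
    has_d = np.isfinite(d)
    clipped = 0
    if has_d.any():
        bins[has_d], clipped = assign_bins(d[has_d], cfg.bins)
    nuclei["bin"] = bins
    for m in image.markers:
        nuclei[f"{m}_ratio"] = normalize_nucleus(nuclei[m].to_numpy(), nuclei["dapi"].to_numpy())
    tallies = {
        "n_nuclei": len(nuclei),
        "n_colonies": len(colonies),
        "n_qualified": len(qualified),
        "n_clipped": clipped,
        "rejections": {c.colony_id: c.rejection_reason for c in colonies
                       if c.qc_status == "rejected"},
    }
    return nuclei, colonies, tallies


def _safe(fn, errors: list, label: str):
    try:
        return fn()
    except (ValueError, KeyError) as exc:
        errors.append(f"{label}: {exc}")
        return None


def run_pipeline(images: dict[str, WellImage], layout: PlateLayout,
                 cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis over a set of wells.

    Statistical comparisons that lack their preconditions (too few lines,
    absent control line, too few positive nuclei) are skipped and recorded
    in the run log rather than failing the whole run.
    """
    cfg = cfg or PipelineConfig()
    unknown = [w for w in images if w not in layout.wells]
    if unknown:
        raise KeyError(f"wells not present in plate layout: {unknown}")

    all_nuclei, all_colonies, prof_rows, pct_rows = [], [], [], []
    well_models: dict[tuple[str, str], PositivityModel] = {}
    log: dict = {"version": __version__, "thresholds": {
        "qc": cfg.qc.__dict__, "alpha_mean_outlier": ALPHA_MEAN_OUTLIER,
        "alpha_radial_outlier": ALPHA_RADIAL_OUTLIER,
    }, "wells": {}, "background": {}, "skipped": []}

    for wid, image in images.items():
        info = layout.wells[wid]
        nuclei, colonies, tallies = process_well(image, cfg)
        log["wells"][wid] = tallies
        nuclei["line"] = info.line
        nuclei["experiment"] = info.experiment
        nuclei["replicate"] = info.replicate
        all_nuclei.append(nuclei)
        ct = colony_table(colonies, wid)
        ct["line"] = info.line
        ct["experiment"] = info.experiment
        all_colonies.append(ct)

        in_colony = nuclei[nuclei["qualified_colony"]]
        for m in image.markers:
            if len(in_colony) >= cfg.min_nuclei_background:
                model = estimate_background(in_colony[f"{m}_ratio"].to_numpy(), marker=m)
            else:
                log["skipped"].append(f"{wid}/{m}: too few nuclei for background estimation")
                continue
            well_models[(wid, m)] = model
            log["background"][f"{wid}/{m}"] = {
                "background": model.background, "threshold": model.threshold,
                "method": model.method,
            }
            colony_profiles = []
            for cid, grp in in_colony.groupby("colony_id"):
                sub = model.subtract(grp[f"{m}_ratio"].to_numpy())
                prof = colony_profile(sub, grp["bin"].to_numpy(), m, cfg.bins,
                                      ids={"well": wid, "colony": cid})
                colony_profiles.append(prof)
                pct_rows.append({
                    "line": info.line, "experiment": info.experiment,
                    "replicate": info.replicate, "well": wid, "colony_id": cid,
                    "marker": m, "n_nuclei": len(grp),
                    "percent_positive": percent_positive(grp[f"{m}_ratio"].to_numpy(), model),
                })
            if not colony_profiles:
                continue
            for prof in well_normalize(colony_profiles):
                for b in range(cfg.bins.n_bins):
                    prof_rows.append({
                        "line": info.line, "experiment": info.experiment,
                        "replicate": info.replicate, "well": wid,
                        "colony_id": prof.ids["colony"], "marker": m, "bin": b + 1,
                        "value": prof.values[b], "n": int(prof.n[b]),
                    })

    nuclei_df = pd.concat(all_nuclei, ignore_index=True) if all_nuclei else pd.DataFrame()
    colonies_df = pd.concat(all_colonies, ignore_index=True) if all_colonies else pd.DataFrame()
    profiles_df = pd.DataFrame(prof_rows)
    pct_df = pd.DataFrame(pct_rows)

    line_prof_rows = []
    if not profiles_df.empty:
        for (line, marker), grp in profiles_df.groupby(["line", "marker"]):
            exp_profiles = []
            for exp, egrp in grp.groupby("experiment"):
                well_profiles = []
                for well, wgrp in egrp.groupby("well"):
                    from .profiling import RadialProfile
                    cols = []
                    for cid, cgrp in wgrp.groupby("colony_id"):
                        v = cgrp.sort_values("bin")["value"].to_numpy()
                        n = cgrp.sort_values("bin")["n"].to_numpy()
                        cols.append(RadialProfile(marker=marker, level="colony",
                                                  values=v, n=n, geometry=cfg.bins))
                    well_profiles.append(aggregate(cols, "well", ids={"well": well}))
                exp_profiles.append(aggregate(well_profiles, "experiment", ids={"experiment": exp}))
            lp = aggregate(exp_profiles, "line", ids={"line": line})
            for b in range(cfg.bins.n_bins):
                line_prof_rows.append({"line": line, "marker": marker, "bin": b + 1,
                                       "value": lp.values[b], "sd": lp.sd[b],
                                       "n": int(lp.n[b])})
    line_profiles_df = pd.DataFrame(line_prof_rows)

    stats_rows = []
    errors: list[str] = []
    markers = sorted(pct_df["marker"].unique()) if not pct_df.empty else []
    for m in markers:
        sub = pct_df[pct_df["marker"] == m]
        by_line = {ln: g["percent_positive"].to_numpy() for ln, g in sub.groupby("line")}
        if len(by_line) >= 3 and all(v.size >= 3 for v in by_line.values()):
            res = _safe(lambda: kruskal_dunn(by_line, marker=m), errors, f"kruskal/{m}")
            if res is not None:
                omnibus, _ = res
                stats_rows.append({"test": omnibus.test, "marker": m, "line": "",
                                   "statistic": omnibus.statistic, "pvalue": omnibus.pvalue,
                                   "significant": omnibus.significant})
        for ln, vals in by_line.items():
            pool = np.concatenate([v for l2, v in by_line.items() if l2 != ln]) \
                if len(by_line) > 1 else np.array([])
            if vals.size >= 3 and pool.size >= 10:
                res = _safe(lambda: outlier_mean_expression(vals, pool, line=ln, marker=m),
                            errors, f"pooled_t/{m}/{ln}")
                if res is not None:
                    stats_rows.append({"test": res.test, "marker": m, "line": ln,
                                       "statistic": res.statistic, "pvalue": res.pvalue,
                                       "significant": res.significant})

    if layout.control_line and not nuclei_df.empty:
        ctrl_wells = [w for w, info in layout.wells.items() if info.line == layout.control_line]
        for m in markers:
            def positive_distances(lines_wells):
                parts = []
                for w in lines_wells:
                    model = well_models.get((w, m))
                    if model is None:
                        continue
                    sub = nuclei_df[(nuclei_df["well"] == w) & nuclei_df["qualified_colony"]]
                    pos = model.is_positive(sub[f"{m}_ratio"].to_numpy())
                    parts.append(sub["distance_um"].to_numpy()[pos])
                return np.concatenate(parts) if parts else np.array([])
            ctrl_d = positive_distances(ctrl_wells)
            for ln in sorted({info.line for info in layout.wells.values()}):
                if ln == layout.control_line:
                    continue
                wells_ln = [w for w, info in layout.wells.items() if info.line == ln]
                res = _safe(lambda: outlier_radial(positive_distances(wells_ln), ctrl_d,
                                                   line=ln, control_line=layout.control_line,
                                                   marker=m),
                            errors, f"ks_vs_control/{m}/{ln}")
                if res is not None:
                    stats_rows.append({"test": res.test, "marker": m, "line": ln,
                                       "statistic": res.statistic, "pvalue": res.pvalue,
                                       "significant": res.significant})
    stats_df = pd.DataFrame(stats_rows,
                            columns=["test", "marker", "line", "statistic",
                                     "pvalue", "significant"])

    corr_df = pd.DataFrame()
    pca_df = pd.DataFrame()
    if not pct_df.empty and len(markers) >= 2:
        wide = pct_df.pivot_table(index=["well", "colony_id"], columns="marker",
                                  values="percent_positive")
        wide = wide.dropna()
        if len(wide) >= 5:
            corr_df = marker_correlations(wide)
        line_means = pct_df.groupby(["line", "marker"])["percent_positive"].mean().unstack()
        if len(line_means) >= 2:
            res = _safe(lambda: pca_lines(line_means), errors, "pca")
            if res is not None:
                pca_df = res.scores
    log["skipped"].extend(errors)
    return PipelineResult(nuclei=nuclei_df, colonies=colonies_df, profiles=profiles_df,
                          percent_positive=pct_df, line_profiles=line_profiles_df,
                          stats=stats_df, correlations=corr_df, pca_scores=pca_df, log=log)
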