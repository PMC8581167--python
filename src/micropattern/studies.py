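"""Validation studies run against the synthetic-data generator's ground truth.

Each study simulates plates (or samples directly from the generator's
positional model), runs the corresponding pipeline stage, and scores the
result against the configured truth. They back the acceptance checks, the
analysis drivers and the documentation figures; all sizes are chosen to
finish on a single CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .colonies import QCThresholds, qc_filter, identify_colonies
from .io import PlateLayout, WellInfo
from .pipeline import PipelineConfig, run_pipeline
from .segmentation import detect_nuclei, measure_intensities
from .simulate import (RadialExpressionModel, SimConfig, generate_plate,
                       generate_variant_table, sample_positive_distances)
from .stats import ks_radial_compare, outlier_mean_expression
from .variants import filter_deleterious, filter_rare

__all__ = ["ring_recovery_study", "qc_study", "ks_calibration_study",
           "kruskal_calibration_study", "ks_power_study",
           "pooled_t_outlier_study", "variant_roundtrip_study"]

RING_CENTER_UM = 425.0
RING_WIDTH_UM = 40.0
UNIFORM_POSITIVE_FRACTION = 0.4


def _recovery_models() -> dict[str, RadialExpressionModel]:
    return {
        "RING": RadialExpressionModel(kind="ring", center_um=RING_CENTER_UM,
                                      width_um=RING_WIDTH_UM, amplitude=1.2,
                                      baseline=0.1, positive_fraction_peak=0.9),
        "UNIF": RadialExpressionModel(kind="uniform", amplitude=1.0, baseline=0.1,
                                      positive_fraction_peak=UNIFORM_POSITIVE_FRACTION),
    }


def _match_colonies(result_colonies: pd.DataFrame, truth_colonies: pd.DataFrame) -> dict:
    """Map (well, detected colony id) -> truth colony row, by nearest centre."""
    matches = {}
    for (well, cid), row in result_colonies.set_index(["well", "colony_id"]).iterrows():
        tw = truth_colonies[truth_colonies["well"] == well]
        d = np.hypot(tw["center_x_um"] - row["centroid_x_um"],
                     tw["center_y_um"] - row["centroid_y_um"])
        matches[(well, cid)] = tw.loc[d.idxmin()]
    return matches


def ring_recovery_study(seed: int, n_wells: int = 4, n_colonies: int = 6,
                        nuclei_per_colony: int = 800) -> dict:
    """End-to-end parameter recovery on a simulated plate.

    One line expressing an outer ring (centre 425 μm, width 40 μm) and a
    uniform marker with positive fraction 0.4. Reports the fraction of
    qualified colonies whose recovered radial peak lands within one 25-μm
    ring of the configured centre, the per-colony percent-positive error
    against the realised ground truth, and the background-level error.
    """
    wells = {f"A{i + 1}": {"line": "uoxz_4"} for i in range(n_wells)}
    cfg = SimConfig(n_colonies_per_well=n_colonies, nuclei_per_colony=nuclei_per_colony,
                    marker_models=_recovery_models(), plate_layout=wells, seed=seed)
    images, truth = generate_plate(cfg, seed=seed)
    layout = PlateLayout(wells={w: WellInfo("uoxz_4", "uoxz") for w in wells},
                         channels={0: "DAPI", 1: "RING", 2: "UNIF"},
                         pixel_size_um=cfg.pixel_size_um)
    result = run_pipeline(images, layout)

    true_peak_bin = int(RING_CENTER_UM // 25.0) + 1
    qualified = result.colonies[result.colonies["qc_status"] == "qualified"]
    matches = _match_colonies(qualified, truth.colonies)

    peak_hits, pct_errors, n_colony_nuclei = [], [], []
    ring = result.profiles[result.profiles["marker"] == "RING"]
    for (well, cid), grp in ring.groupby(["well", "colony_id"]):
        occ = grp[grp["n"] > 0]
        peak = int(occ.loc[occ["value"].idxmax(), "bin"])
        peak_hits.append(abs(peak - true_peak_bin) <= 1)
    pct = result.percent_positive
    for _, row in pct[pct["marker"] == "UNIF"].iterrows():
        tc = matches[(row["well"], row["colony_id"])]
        tn = truth.nuclei[(truth.nuclei["well"] == row["well"])
                          & (truth.nuclei["colony_id"] == tc["colony_id"])]
        truth_pct = 100.0 * tn["UNIF_positive_true"].mean()
        pct_errors.append(abs(row["percent_positive"] - truth_pct))
        n_colony_nuclei.append(len(tn))
    bg_errors = [abs(v["background"] - 0.1)
                 for k, v in result.log["background"].items()]
    return {
        "n_colonies_scored": len(peak_hits),
        "peak_bin_within_one_rate": float(np.mean(peak_hits)),
        "percent_positive_max_abs_error": float(np.max(pct_errors)),
        "percent_positive_mean_abs_error": float(np.mean(pct_errors)),
        "background_max_abs_error": float(np.max(bg_errors)),
        "mean_nuclei_per_colony": float(np.mean(n_colony_nuclei)),
    }


def qc_study(seed: int, n_wells: int = 4, n_colonies: int = 6,
             nuclei_per_colony: int = 500, fraction_truncated: float = 0.3) -> dict:
    """QC correctness on plates where 30% of colonies cross the image border."""
    wells = {f"A{i + 1}": {"line": "x"} for i in range(n_wells)}
    cfg = SimConfig(n_colonies_per_well=n_colonies, nuclei_per_colony=nuclei_per_colony,
                    fraction_truncated=fraction_truncated, marker_models={},
                    plate_layout=wells, seed=seed)
    images, truth = generate_plate(cfg, seed=seed)
    thresholds = QCThresholds()
    rows = []
    for wid, image in images.items():
        seg = detect_nuclei(image)
        seg.table = measure_intensities(image, seg)
        colonies, _, _ = identify_colonies(seg, image)
        colonies = qc_filter(colonies, thresholds)
        tw = truth.colonies[truth.colonies["well"] == wid]
        for c in colonies:
            if c.n_nuclei < 10:
                continue
            d = np.hypot(tw["center_x_um"] - c.centroid_x_um,
                         tw["center_y_um"] - c.centroid_y_um)
            rows.append({"truncated": bool(tw.loc[d.idxmin(), "truncated"]),
                         "qualified": c.qc_status == "qualified"})
    df = pd.DataFrame(rows)
    truncated = df[df["truncated"]]
    complete = df[~df["truncated"]]
    return {
        "n_truncated": len(truncated),
        "n_complete": len(complete),
        "truncated_rejected_rate": float((~truncated["qualified"]).mean()),
        "complete_qualified_rate": float(complete["qualified"].mean()),
    }


def ks_calibration_study(seed: int, n_sims: int = 1000, n: int = 200,
                         alpha: float = 0.05) -> dict:
    """Type-I error of the radial KS test on same-ring null draws."""
    rng = np.random.default_rng(seed)
    model = RadialExpressionModel(kind="ring", center_um=RING_CENTER_UM,
                                  width_um=RING_WIDTH_UM)
    hits = 0
    for _ in range(n_sims):
        a = sample_positive_distances(model, n, rng)
        b = sample_positive_distances(model, n, rng)
        hits += ks_radial_compare(a, b, alpha=alpha).significant
    return {"n_sims": n_sims, "alpha": alpha, "rejection_rate": hits / n_sims}


def ks_power_study(seed: int, n_sims: int = 200, n: int = 200,
                   shift_um: float = 100.0, alpha: float = 0.01) -> dict:
    """Power of the radial KS test for a ring-centre shift (default 100 μm)."""
    rng = np.random.default_rng(seed)
    m1 = RadialExpressionModel(kind="ring", center_um=RING_CENTER_UM - shift_um,
                               width_um=RING_WIDTH_UM)
    m2 = RadialExpressionModel(kind="ring", center_um=RING_CENTER_UM,
                               width_um=RING_WIDTH_UM)
    hits = 0
    for _ in range(n_sims):
        a = sample_positive_distances(m1, n, rng)
        b = sample_positive_distances(m2, n, rng)
        hits += ks_radial_compare(a, b, alpha=alpha).significant
    return {"n_sims": n_sims, "alpha": alpha, "power": hits / n_sims}


def kruskal_calibration_study(seed: int, n_sims: int = 1000, n_lines: int = 4,
                              n_colonies: int = 10, alpha: float = 0.05) -> dict:
    """Type-I error of the omnibus Kruskal-Wallis on identical lines."""
    from scipy import stats as sps
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        groups = [rng.normal(30.0, 5.0, n_colonies) for _ in range(n_lines)]
        hits += sps.kruskal(*groups)[1] < alpha
    return {"n_sims": n_sims, "alpha": alpha, "rejection_rate": hits / n_sims}


def pooled_t_outlier_study(seed: int, n_sims: int = 200, n_lines: int = 8,
                           n_colonies: int = 8, sd: float = 4.0,
                           shift_sd: float = 5.0) -> dict:
    """Detection rate of the pooled-t outlier rule for a shifted line.

    One line's percent-positive mean is shifted by ``shift_sd`` standard
    deviations; the study reports how often that line trips the p < 0.001
    rule and how often any unshifted line does (false flags).
    """
    rng = np.random.default_rng(seed)
    detected = 0
    false_flags = 0
    null_tests = 0
    for _ in range(n_sims):
        lines = [rng.normal(30.0, sd, n_colonies) for _ in range(n_lines)]
        lines[0] = lines[0] + shift_sd * sd
        for i, vals in enumerate(lines):
            pool = np.concatenate([v for j, v in enumerate(lines) if j != i])
            res = outlier_mean_expression(vals, pool)
            if i == 0:
                detected += res.significant
            else:
                false_flags += res.significant
                null_tests += 1
    return {"n_sims": n_sims, "detection_rate": detected / n_sims,
            "false_flag_rate": false_flags / null_tests}


def variant_roundtrip_study(seed: int, tuples=((5, 3, 2, 1), (0, 0, 0, 0),
                                               (2, 0, 0, 0), (7, 5, 5, 5))) -> dict:
    """Filter survivors must equal the generator's constructed pass count."""
    exact = True
    total_pass = 0
    for counts in tuples:
        table = generate_variant_table(*counts, seed=seed)
        out = filter_deleterious(filter_rare(table))
        exact &= (len(out) == counts[0])
        total_pass += len(out)
    return {"all_tuples_exact": bool(exact), "total_survivors": total_pass,
            "total_constructed": sum(c[0] for c in tuples)}
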