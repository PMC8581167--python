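"""Ground-truthed synthetic plates of micropatterned germ-layer colonies.

Generates multi-channel well images (DAPI + marker channels) in which nuclei
are placed inside 1000-μm circular colonies and express markers in radially
ordered domains: an ectoderm-like dome in the colony centre (SOX2), a
mesoderm-like mid-ring (BRA) and an endoderm-like outer ring with angular
discontinuities (SOX17). Every image comes with a :class:`GroundTruth`
carrying the true nucleus positions, marker positivity and colony geometry,
so every downstream stage of the pipeline can be scored against truth.

The intensity model is multiplicative in DAPI: a nucleus's marker intensity
is ``ratio * dapi`` where ``ratio = baseline + positive * amplitude *
g(D)`` and ``g`` is a Gaussian radial envelope. The DAPI normalisation used
by the analysis is therefore exactly invertible in the noiseless limit.
Non-expressing nuclei emit baseline-level marker signal, which defines the
background population the pipeline must estimate and subtract.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import WellImage

__all__ = [
    "RadialExpressionModel",
    "DonorEffect",
    "SimConfig",
    "GroundTruth",
    "default_marker_models",
    "generate_well",
    "generate_plate",
    "generate_variant_table",
    "sample_positive_distances",
    "ADHESION_GENES",
    "GERM_LAYER_GENES",
]

# Genes the variant analysis groups into functional sets.
ADHESION_GENES = ("ITGB1", "ITGA6", "FHL2")
GERM_LAYER_GENES = ("SMAD2", "FGFR1", "TBXT")


@dataclass(frozen=True)
class RadialExpressionModel:
    """Radial expression domain for one marker.

    ``kind`` selects the envelope: ``center_dome`` (monotone decreasing from
    the colony centre), ``ring`` (Gaussian annulus at ``center_um``) or
    ``uniform`` (no radial structure). ``positive_fraction_peak`` is the
    probability that a nucleus at the envelope peak is marker-positive; the
    probability decays with the same envelope. ``discontinuity_fraction`` is
    the angular fraction of a ring left unexpressed, emulating the broken
    outer endoderm ring seen in micropatterned colonies.
    """

    kind: str = "ring"
    center_um: float = 425.0
    width_um: float = 40.0
    amplitude: float = 1.0
    baseline: float = 0.1
    positive_fraction_peak: float = 0.9
    discontinuity_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("center_dome", "ring", "uniform"):
            raise ValueError(f"unknown radial model kind {self.kind!r}")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("intensity amplitudes must be >= 0")
        if not 0.0 <= self.positive_fraction_peak <= 1.0:
            raise ValueError("positive_fraction_peak must be in [0, 1]")
        if not 0.0 <= self.discontinuity_fraction < 1.0:
            raise ValueError("discontinuity_fraction must be in [0, 1)")

    def envelope(self, d: np.ndarray) -> np.ndarray:
        """Radial envelope g(D) in [0, 1]."""
        d = np.asarray(d, dtype=float)
        if self.kind == "uniform":
            return np.ones_like(d)
        if self.kind == "center_dome":
            return np.exp(-(d**2) / (2.0 * self.width_um**2))
        return np.exp(-((d - self.center_um) ** 2) / (2.0 * self.width_um**2))

    def expression_ratio(self, d: np.ndarray, positive: np.ndarray) -> np.ndarray:
        """Marker/DAPI intensity ratio for nuclei at distance ``d``."""
        return self.baseline + np.asarray(positive, dtype=float) * self.amplitude * self.envelope(d)

    def positive_fraction(self, d: np.ndarray) -> np.ndarray:
        """Probability that a nucleus at distance ``d`` is marker-positive."""
        return self.positive_fraction_peak * self.envelope(d)

    def expected_bin_profile(self, bin_width: float = 25.0, n_bins: int = 20) -> np.ndarray:
        """Expected background-subtracted ratio at each bin centre."""
        centers = (np.arange(n_bins) + 0.5) * bin_width
        p = self.positive_fraction(centers) * (1.0 - self.discontinuity_fraction)
        return p * self.amplitude * self.envelope(centers)

    def true_peak_bin(self, bin_width: float = 25.0, n_bins: int = 20) -> int:
        """1-based index of the bin with highest expected expression."""
        return int(np.argmax(self.expected_bin_profile(bin_width, n_bins))) + 1


@dataclass(frozen=True)
class DonorEffect:
    """Per-donor perturbation of one marker's radial domain."""

    center_shift_um: float = 0.0
    width_scale: float = 1.0
    amplitude_scale: float = 1.0
    positive_scale: float = 1.0

    def apply(self, model: RadialExpressionModel) -> RadialExpressionModel:
        return dataclasses.replace(
            model,
            center_um=model.center_um + self.center_shift_um,
            width_um=model.width_um * self.width_scale,
            amplitude=model.amplitude * self.amplitude_scale,
            positive_fraction_peak=min(1.0, model.positive_fraction_peak * self.positive_scale),
        )


def default_marker_models() -> dict[str, RadialExpressionModel]:
    """Marker domains emulating the radially ordered germ layers.

    SOX2 (ectoderm) is a central dome, BRA (mesoderm) a mid-ring and SOX17
    (endoderm) an outer ring with angular discontinuities.
    """
    return {
        "SOX2": RadialExpressionModel(
            kind="center_dome", center_um=0.0, width_um=150.0,
            amplitude=1.0, baseline=0.1, positive_fraction_peak=0.9,
        ),
        "BRA": RadialExpressionModel(
            kind="ring", center_um=250.0, width_um=60.0,
            amplitude=1.0, baseline=0.1, positive_fraction_peak=0.85,
        ),
        "SOX17": RadialExpressionModel(
            kind="ring", center_um=425.0, width_um=40.0,
            amplitude=1.2, baseline=0.1, positive_fraction_peak=0.9,
            discontinuity_fraction=0.2,
        ),
    }


@dataclass
class SimConfig:
    """Conditions for one simulated plate.

    Defaults emulate the physical assay: 1000-μm colonies on a 96-well
    micropatterned plate, ~800 nuclei per colony, four to seven readable
    colonies per well.
    """

    pixel_size_um: float = 2.0
    colony_diameter_um: float = 1000.0
    n_colonies_per_well: int = 6
    fraction_truncated: float = 0.0
    nuclei_per_colony: int = 800
    nucleus_radius_um: float = 6.0
    marker_models: dict[str, RadialExpressionModel] = field(default_factory=default_marker_models)
    noise_sd: float = 5.0
    dapi_mean: float = 400.0
    dapi_cv: float = 0.2
    donor_effects: dict[str, dict[str, DonorEffect]] = field(default_factory=dict)
    plate_layout: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.colony_diameter_um <= 0:
            raise ValueError("colony_diameter_um must be > 0")
        if not 0.0 <= self.fraction_truncated <= 1.0:
            raise ValueError("fraction_truncated must be in [0, 1]")
        if self.nuclei_per_colony < 0 or self.n_colonies_per_well < 1:
            raise ValueError("colony/nucleus counts must be positive")

    @property
    def colony_radius_um(self) -> float:
        return self.colony_diameter_um / 2.0

    def models_for_line(self, line: str) -> dict[str, RadialExpressionModel]:
        """Marker models with this line's donor effects applied."""
        effects = self.donor_effects.get(line, {})
        return {
            m: effects[m].apply(model) if m in effects else model
            for m, model in self.marker_models.items()
        }


@dataclass
class GroundTruth:
    """Truth tables accompanying simulated images.

    ``nuclei``: one row per rendered nucleus (well, colony, position, DAPI,
    per-marker true ratio and positivity, true radial distance and bin).
    ``colonies``: one row per colony (centre, truncation flag).
    ``expected_profiles``: per well/marker/bin expected subtracted ratio.
    """

    nuclei: pd.DataFrame
    colonies: pd.DataFrame
    expected_profiles: pd.DataFrame

    @staticmethod
    def concat(parts: list["GroundTruth"]) -> "GroundTruth":
        return GroundTruth(
            nuclei=pd.concat([p.nuclei for p in parts], ignore_index=True),
            colonies=pd.concat([p.colonies for p in parts], ignore_index=True),
            expected_profiles=pd.concat(
                [p.expected_profiles for p in parts], ignore_index=True
            ),
        )


def _place_nuclei(rng: np.random.Generator, n: int, radius: float,
                  min_spacing: float, max_rounds: int = 80) -> np.ndarray:
    """Uniform positions in a disc with minimum pairwise spacing.

    Batch rejection sampling against an occupancy grid; raises if the
    requested density cannot be placed.
    """
    if n == 0:
        return np.empty((0, 2))
    cell = min_spacing / math.sqrt(2.0)
    ngrid = int(math.ceil(2.0 * radius / cell)) + 7
    grid = -np.ones((ngrid, ngrid), dtype=int)
    pts = np.empty((n, 2))
    placed = 0
    for _ in range(max_rounds):
        todo = n - placed
        if todo == 0:
            break
        r = radius * np.sqrt(rng.random(2 * todo))
        th = rng.random(2 * todo) * 2.0 * np.pi
        cand = np.column_stack([r * np.cos(th), r * np.sin(th)])
        for p in cand:
            if placed == n:
                break
            gi = int((p[0] + radius) / cell) + 3
            gj = int((p[1] + radius) / cell) + 3
            ok = True
            for di in (-2, -1, 0, 1, 2):
                for dj in (-2, -1, 0, 1, 2):
                    k = grid[gi + di, gj + dj]
                    if k >= 0 and np.hypot(*(pts[k] - p)) < min_spacing:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                pts[placed] = p
                grid[gi, gj] = placed
                placed += 1
    if placed < n:
        raise ValueError(
            f"could not place nuclei_per_colony={n} nuclei at spacing "
            f"{min_spacing:.1f} um in a {radius:.0f}-um colony; "
            "reduce nuclei_per_colony or nucleus_radius_um"
        )
    return pts


def _colony_centers(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Colony centres on a jittered grid; truncated ones pushed across the border.

    Returns (centers_um, truncated_flags, width_um, height_um).
    """
    n = cfg.n_colonies_per_well
    R = cfg.colony_radius_um
    spacing = 2.6 * R
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    width = ncols * spacing
    height = nrows * spacing
    centers = []
    for k in range(n):
        i, j = divmod(k, ncols)
        cx = (j + 0.5) * spacing + rng.uniform(-0.1, 0.1) * R
        cy = (i + 0.5) * spacing + rng.uniform(-0.1, 0.1) * R
        centers.append((cx, cy))
    centers = np.array(centers)
    n_trunc = int(round(cfg.fraction_truncated * n))
    truncated = np.zeros(n, dtype=bool)
    if n_trunc:
        order = rng.permutation(n)[:n_trunc]
        for k in order:
            cx, cy = centers[k]
            # distance of centre to each border; push across the nearest one
            dists = np.array([cx, width - cx, cy, height - cy])
            side = int(np.argmin(dists))
            keep = rng.uniform(0.2, 0.7) * R  # centre this far inside
            if side == 0:
                centers[k, 0] = keep
            elif side == 1:
                centers[k, 0] = width - keep
            elif side == 2:
                centers[k, 1] = keep
            else:
                centers[k, 1] = height - keep
            truncated[k] = True
    return centers, truncated, width, height


def _render_channel(shape: tuple[int, int], xs_px: np.ndarray, ys_px: np.ndarray,
                    radius_px: float, values: np.ndarray) -> np.ndarray:
    """Paint nuclei as filled discs (max composition), one channel."""
    img = np.zeros(shape, dtype=np.float64)
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (xx**2 + yy**2) <= radius_px**2
    h, w = shape
    for x, y, v in zip(xs_px, ys_px, values):
        cx, cy = int(round(x)), int(round(y))
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        sy0, sy1 = max(0, -y0), 2 * r + 1 - max(0, y1 - h)
        sx0, sx1 = max(0, -x0), 2 * r + 1 - max(0, x1 - w)
        if sy0 >= sy1 or sx0 >= sx1:
            continue
        view = img[max(0, y0):min(h, y1), max(0, x0):min(w, x1)]
        sub = disc[sy0:sy1, sx0:sx1]
        np.maximum(view, np.where(sub, v, 0.0), out=view)
    return img


def generate_well(cfg: SimConfig, well_id: str, seed: int | None = None,
                  line: str | None = None) -> tuple[WellImage, GroundTruth]:
    """Simulate one well: a multi-channel image plus its ground truth.

    ``line`` selects which donor effects apply; when omitted it is looked up
    in ``cfg.plate_layout`` (falling back to no donor effect).
    """
    if cfg.plate_layout and well_id not in cfg.plate_layout and line is None:
        raise KeyError(f"well {well_id!r} not present in plate_layout")
    if line is None:
        line = cfg.plate_layout.get(well_id, {}).get("line", "")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    models = cfg.models_for_line(line)
    markers = list(models)
    R = cfg.colony_radius_um
    px = cfg.pixel_size_um
    r_nuc = cfg.nucleus_radius_um

    centers, truncated, width_um, height_um = _colony_centers(cfg, rng)
    shape = (int(round(height_um / px)), int(round(width_um / px)))

    rows = []
    min_spacing = 2.5 * r_nuc  # clear inter-nucleus gap so discs stay resolvable
    for cid, ((cx, cy), trunc) in enumerate(zip(centers, truncated), start=1):
        # keep nuclei fully inside the nominal disc
        pts = _place_nuclei(rng, cfg.nuclei_per_colony, R - r_nuc, min_spacing)
        xs = pts[:, 0] + cx
        ys = pts[:, 1] + cy
        # drop nuclei that would render partially outside the image
        inside = ((xs >= r_nuc) & (xs <= width_um - r_nuc)
                  & (ys >= r_nuc) & (ys <= height_um - r_nuc))
        xs, ys = xs[inside], ys[inside]
        d = np.hypot(xs - cx, ys - cy)
        theta = np.mod(np.arctan2(ys - cy, xs - cx), 2.0 * np.pi)
        shape_k = cfg.dapi_cv**-2
        dapi = rng.gamma(shape_k, cfg.dapi_mean / shape_k, size=d.size)
        rec = {
            "well": well_id, "line": line, "colony_id": cid,
            "x_um": xs, "y_um": ys, "distance_um": d,
            "truncated_colony": trunc, "dapi_true": dapi,
        }
        disc_offset = rng.uniform(0.0, 2.0 * np.pi)
        for m in markers:
            model = models[m]
            p = model.positive_fraction(d)
            positive = rng.random(d.size) < p
            if model.kind == "ring" and model.discontinuity_fraction > 0:
                ang = np.mod(theta - disc_offset, 2.0 * np.pi)
                in_gap = ang < 2.0 * np.pi * model.discontinuity_fraction
                positive = positive & ~in_gap
            ratio = model.expression_ratio(d, positive)
            rec[f"{m}_positive_true"] = positive
            rec[f"{m}_ratio_true"] = ratio
        rows.append(pd.DataFrame(rec))
    nuclei = pd.concat(rows, ignore_index=True)
    nuclei.insert(0, "nucleus_id", np.arange(len(nuclei)))
    nuclei["bin_true"] = np.minimum(np.floor(nuclei["distance_um"] / 25.0).astype(int) + 1, 20)

    xs_px = nuclei["x_um"].to_numpy() / px
    ys_px = nuclei["y_um"].to_numpy() / px
    r_px = r_nuc / px
    channels = {"DAPI": _render_channel(shape, xs_px, ys_px, r_px, nuclei["dapi_true"].to_numpy())}
    for m in markers:
        vals = nuclei[f"{m}_ratio_true"].to_numpy() * nuclei["dapi_true"].to_numpy()
        channels[m] = _render_channel(shape, xs_px, ys_px, r_px, vals)
    for name in channels:
        img = ndimage.gaussian_filter(channels[name], sigma=1.0)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    stack = np.stack([channels[c] for c in ["DAPI", *markers]]).astype(np.float32)
    image = WellImage(pixels=stack, channel_names=["DAPI", *markers],
                      pixel_size_um=px, well_id=well_id)

    colonies = pd.DataFrame({
        "well": well_id, "line": line,
        "colony_id": np.arange(1, cfg.n_colonies_per_well + 1),
        "center_x_um": centers[:, 0], "center_y_um": centers[:, 1],
        "truncated": truncated,
    })
    prof_rows = []
    for m in markers:
        expected = models[m].expected_bin_profile()
        for b, v in enumerate(expected, start=1):
            prof_rows.append({"well": well_id, "line": line, "marker": m,
                              "bin": b, "expected_ratio": v})
    truth = GroundTruth(nuclei=nuclei, colonies=colonies,
                        expected_profiles=pd.DataFrame(prof_rows))
    return image, truth


def generate_plate(cfg: SimConfig, seed: int | None = None) -> tuple[dict[str, WellImage], GroundTruth]:
    """Simulate every well in ``cfg.plate_layout``.

    Wells of the same line share donor effects (they are part of the config);
    replicate wells differ only by their RNG stream, which is derived
    deterministically from the top-level seed and the well's position in the
    layout.
    """
    if not cfg.plate_layout:
        raise ValueError("plate_layout is empty")
    well_ids = list(cfg.plate_layout)
    if len(set(well_ids)) != len(well_ids):
        raise ValueError("duplicate well ids in plate_layout")
    base = cfg.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(base).generate_state(len(well_ids)) % (2**31)
    images: dict[str, WellImage] = {}
    truths: list[GroundTruth] = []
    for wid, wseed in zip(well_ids, child_seeds):
        img, truth = generate_well(cfg, wid, seed=int(wseed))
        images[wid] = img
        truths.append(truth)
    return images, GroundTruth.concat(truths)


def sample_positive_distances(model: RadialExpressionModel, n: int,
                              rng: np.random.Generator,
                              colony_radius_um: float = 500.0) -> np.ndarray:
    """Radial distances of marker-positive nuclei under the generator's model.

    Nuclei are uniform over the colony disc and positive with probability
    ``model.positive_fraction(D)``; rejection sampling draws exactly the
    distance distribution the image generator produces, without rendering.
    """
    out = np.empty(0)
    while out.size < n:
        r = colony_radius_um * np.sqrt(rng.random(4 * n))
        keep = rng.random(r.size) < model.positive_fraction(r)
        out = np.concatenate([out, r[keep]])
    return out[:n]


_SYNTH_DONORS = ("aaaa", "bbbb", "cccc", "dddd", "eeee", "ffff", "gggg", "hhhh")


def generate_variant_table(n_pass: int, n_fail_maf: int, n_fail_condel: int,
                           n_fail_linecount: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic annotated nsSNV table with known filter outcomes.

    Exactly ``n_pass`` rows satisfy all three selection rules (MAF < 0.005 in
    both population databases, carried by fewer than five lines, Condel
    deleterious); each failure class violates exactly its designated rule,
    including the boundary cases MAF = 0.005 and line count = 5. The
    ``true_pass`` column is the constructed ground truth.
    """
    for name, v in [("n_pass", n_pass), ("n_fail_maf", n_fail_maf),
                    ("n_fail_condel", n_fail_condel), ("n_fail_linecount", n_fail_linecount)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(ADHESION_GENES + GERM_LAYER_GENES)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows = []

    def base_row(i: int) -> dict:
        donor = _SYNTH_DONORS[i % len(_SYNTH_DONORS)]
        gene = genes[i % len(genes)]
        pos = int(rng.integers(10, 900))
        sub = f"p.{aas[rng.integers(20)]}{pos}{aas[rng.integers(20)]}"
        return {"gene": gene, "substitution": sub, "donor": donor,
                "carrier_lines": f"{donor}_{1 + i % 4}",
                "duet_ddg": float(np.round(rng.normal(-0.8, 0.6), 3))}

    i = 0
    for _ in range(n_pass):
        r = base_row(i); i += 1
        r.update(maf_1000g=float(rng.uniform(0, 0.0049)),
                 maf_exac=float(rng.uniform(0, 0.0049)),
                 n_hipsci_lines=int(rng.integers(1, 5)),
                 condel_class="deleterious", true_pass=True,
                 fail_class="none")
        rows.append(r)
    for j in range(n_fail_maf):
        r = base_row(i); i += 1
        # first row sits exactly on the exclusive MAF boundary
        bad = 0.005 if j == 0 else float(rng.uniform(0.005, 0.2))
        which = rng.integers(3)
        r.update(maf_1000g=bad if which != 1 else float(rng.uniform(0, 0.0049)),
                 maf_exac=bad if which != 0 else float(rng.uniform(0, 0.0049)),
                 n_hipsci_lines=int(rng.integers(1, 5)),
                 condel_class="deleterious", true_pass=False,
                 fail_class="maf")
        rows.append(r)
    for _ in range(n_fail_condel):
        r = base_row(i); i += 1
        r.update(maf_1000g=float(rng.uniform(0, 0.0049)),
                 maf_exac=float(rng.uniform(0, 0.0049)),
                 n_hipsci_lines=int(rng.integers(1, 5)),
                 condel_class="neutral", true_pass=False,
                 fail_class="condel")
        rows.append(r)
    for j in range(n_fail_linecount):
        r = base_row(i); i += 1
        # first row sits exactly on the exclusive line-count boundary
        r.update(maf_1000g=float(rng.uniform(0, 0.0049)),
                 maf_exac=float(rng.uniform(0, 0.0049)),
                 n_hipsci_lines=5 if j == 0 else int(rng.integers(5, 13)),
                 condel_class="deleterious", true_pass=False,
                 fail_class="line_count")
        rows.append(r)
    cols = ["gene", "substitution", "maf_1000g", "maf_exac", "n_hipsci_lines",
            "condel_class", "duet_ddg", "carrier_lines", "donor",
            "true_pass", "fail_class"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
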