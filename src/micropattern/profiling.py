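"""Radial expression profiling of qualified colonies.

Each nucleus is assigned to one of 20 concentric 25-μm rings by its distance
from the colony centroid, so the rings exactly tile the 500-μm radius of the
nominal 1000-μm colony. Expression is processed in a fixed order:

1. per-nucleus DAPI normalisation (marker mean / DAPI mean),
2. background subtraction, with the background level estimated per well and
   marker from the low mode of a two-component Gaussian mixture over the
   per-nucleus ratios,
3. per-bin mean within each colony (empty bins are missing, not zero),
4. scaling by the maximum bin value across colonies of the well, so the
   brightest bin in each well is exactly 1,
5. hierarchical aggregation: colonies → well (technical replicate) →
   experiment (biological replicate) → line, with the SD taken over the
   units being averaged.

Percent-positive per colony — the fraction of nuclei whose subtracted ratio
clears the positivity threshold — controls for cell-number variation
between colonies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = ["BinGeometry", "PositivityModel", "RadialProfile",
           "nucleus_distance", "assign_bin", "assign_bins",
           "normalize_nucleus", "estimate_background", "subtract_background",
           "colony_profile", "well_normalize", "aggregate", "percent_positive"]


@dataclass(frozen=True)
class BinGeometry:
    """Concentric ring binning: ``n_bins`` half-open rings of ``bin_width_um``."""

    bin_width_um: float = 25.0
    n_bins: int = 20

    @property
    def max_radius_um(self) -> float:
        return self.bin_width_um * self.n_bins

    @property
    def edges_um(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_um

    @property
    def centers_um(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_um


DEFAULT_BINS = BinGeometry()


def nucleus_distance(nucleus_xy: tuple[float, float],
                     colony_xy: tuple[float, float]) -> float:
    """Euclidean distance D (μm) of a nucleus from its colony centroid."""
    return math.hypot(nucleus_xy[0] - colony_xy[0], nucleus_xy[1] - colony_xy[1])


def assign_bin(d: float, bin_width: float = 25.0, n_bins: int = 20) -> int:
    """Ring index B for distance D: half-open rings [(B−1)·w, B·w), 1-based.

    Distances beyond the outermost edge (segmentation jitter past the
    nominal colony radius) are clipped into the last ring and logged.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    b = int(d // bin_width) + 1
    if b > n_bins:
        logger.warning("distance %.1f um beyond outer ring; clipped into bin %d", d, n_bins)
        return n_bins
    return b


def assign_bins(distances: np.ndarray, geometry: BinGeometry = DEFAULT_BINS) -> tuple[np.ndarray, int]:
    """Vectorised ring assignment; returns (bins, number clipped into the outer ring)."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    raw = np.floor(d / geometry.bin_width_um).astype(int) + 1
    n_clipped = int(np.sum(raw > geometry.n_bins))
    if n_clipped:
        logger.warning("%d nuclei beyond %g um clipped into bin %d",
                       n_clipped, geometry.max_radius_um, geometry.n_bins)
    return np.minimum(raw, geometry.n_bins), n_clipped


def normalize_nucleus(marker_intensity: float | np.ndarray,
                      dapi_intensity: float | np.ndarray) -> float | np.ndarray:
    """DAPI-normalised expression: marker mean / DAPI mean (scale invariant)."""
    dapi = np.asarray(dapi_intensity, dtype=float)
    if np.any(dapi <= 0):
        raise ValueError("DAPI intensity must be > 0 (zero-DAPI nuclei are dropped upstream)")
    return np.asarray(marker_intensity, dtype=float) / dapi


@dataclass(frozen=True)
class PositivityModel:
    """Background level and positivity threshold for one marker in one well."""

    marker: str
    background: float
    threshold: float
    method: str = "gmm"

    def __post_init__(self) -> None:
        if not 0 <= self.background <= self.threshold:
            raise ValueError("need threshold >= background >= 0")

    def subtract(self, ratios: np.ndarray) -> np.ndarray:
        """Background-subtracted ratio, floored at zero."""
        return np.maximum(np.asarray(ratios, dtype=float) - self.background, 0.0)

    def is_positive(self, ratios: np.ndarray) -> np.ndarray:
        """Positive iff the background-subtracted ratio clears the threshold."""
        return self.subtract(ratios) > self.threshold


def estimate_background(ratios: np.ndarray, marker: str = "",
                        min_nuclei: int = 50) -> PositivityModel:
    """Estimate the non-expressing background mode of a ratio distribution.

    Fits a two-component Gaussian mixture; the background is the mean of the
    lower component and the positivity threshold its mean + 2 SD. If the fit
    degenerates (near-empty component, or modes indistinguishable) it falls
    back to percentiles (5th for the background, 50th for the threshold)
    with a logged warning.
    """
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < min_nuclei:
        raise ValueError(f"need >= {min_nuclei} nuclei to estimate background, got {r.size}")
    try:
        gm = GaussianMixture(n_components=2, random_state=0, n_init=2)
        gm.fit(r.reshape(-1, 1))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        lo = int(np.argmin(means))
        if gm.weights_.min() < 0.02 or abs(means[1] - means[0]) <= 1e-8 + 1e-3 * sds.max():
            raise RuntimeError("degenerate mixture")
        background = float(means[lo])
        threshold = float(means[lo] + 2.0 * sds[lo])
        method = "gmm"
    except Exception:
        logger.warning("mixture fit degenerate for %s; falling back to percentiles", marker)
        background = float(np.percentile(r, 5))
        threshold = float(np.percentile(r, 50))
        method = "percentile"
    background = max(0.0, background)
    threshold = max(threshold, background)
    return PositivityModel(marker=marker, background=background,
                           threshold=threshold, method=method)


def subtract_background(ratios: np.ndarray, model: PositivityModel) -> np.ndarray:
    return model.subtract(ratios)


@dataclass
class RadialProfile:
    """Per-bin mean normalised expression for one marker at one level.

    ``values`` holds NaN for empty bins (missing, not zero); ``sd`` is only
    populated for aggregated profiles; ``n`` counts nuclei (colony level) or
    contributing units (aggregated levels) per bin.
    """

    marker: str
    level: str                      # colony | well | experiment | line
    values: np.ndarray
    n: np.ndarray
    sd: np.ndarray | None = None
    geometry: BinGeometry = field(default_factory=BinGeometry)
    ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n = np.asarray(self.n)
        if self.values.shape != (self.geometry.n_bins,):
            raise ValueError("profile length must equal the number of bins")

    def peak_bin(self) -> int:
        """1-based bin of maximum expression (NaN bins ignored)."""
        if np.all(np.isnan(self.values)):
            raise ValueError("profile has no occupied bins")
        return int(np.nanargmax(self.values)) + 1


def colony_profile(subtracted_ratios: np.ndarray, bins: np.ndarray, marker: str,
                   geometry: BinGeometry = DEFAULT_BINS, ids: dict | None = None) -> RadialProfile:
    """Per-bin mean background-subtracted ratio for one qualified colony."""
    ratios = np.asarray(subtracted_ratios, dtype=float)
    bins = np.asarray(bins, dtype=int)
    if ratios.size == 0:
        raise ValueError("colony has no nuclei")
    if ratios.shape != bins.shape:
        raise ValueError("ratios and bins must align")
    values = np.full(geometry.n_bins, np.nan)
    counts = np.zeros(geometry.n_bins, dtype=int)
    for b in range(1, geometry.n_bins + 1):
        sel = bins == b
        counts[b - 1] = sel.sum()
        if counts[b - 1]:
            values[b - 1] = ratios[sel].mean()
    return RadialProfile(marker=marker, level="colony", values=values,
                         n=counts, geometry=geometry, ids=ids or {})


def well_normalize(profiles: list[RadialProfile]) -> list[RadialProfile]:
    """Scale colony profiles by the maximum bin value across the well.

    After normalisation the brightest bin of the brightest colony is exactly
    1. Idempotent. An all-zero well is left untouched with a warning.
    """
    if not profiles:
        raise ValueError("need at least one colony profile")
    marker = profiles[0].marker
    if any(p.marker != marker for p in profiles):
        raise ValueError("profiles mix markers")
    well_max = np.nanmax([np.nanmax(p.values) if not np.all(np.isnan(p.values)) else np.nan
                          for p in profiles])
    if not np.isfinite(well_max) or well_max <= 0:
        logger.warning("all-zero well for %s; skipping well normalisation", marker)
        return profiles
    return [RadialProfile(marker=p.marker, level=p.level, values=p.values / well_max,
                          n=p.n, sd=p.sd, geometry=p.geometry, ids=dict(p.ids))
            for p in profiles]


_LEVELS = ("colony", "well", "experiment", "line")


def aggregate(profiles: list[RadialProfile], level: str, ids: dict | None = None) -> RadialProfile:
    """Average profiles one level up the replicate hierarchy.

    The mean and SD are taken per bin over the input units (colonies for a
    well profile, wells for an experiment profile, experiments for a line
    profile); bins missing in an input stay out of that bin's mean, and bins
    missing everywhere propagate as missing.
    """
    if not profiles:
        raise ValueError("nothing to aggregate")
    if level not in _LEVELS[1:]:
        raise ValueError(f"level must be one of {_LEVELS[1:]}")
    marker = profiles[0].marker
    geom = profiles[0].geometry
    for p in profiles:
        if p.marker != marker:
            raise ValueError("profiles mix markers")
        if p.geometry != geom:
            raise ValueError("profiles mix bin geometries")
    stack = np.vstack([p.values for p in profiles])
    n = np.sum(~np.isnan(stack), axis=0)
    mean = np.full(stack.shape[1], np.nan)
    sd = np.full(stack.shape[1], np.nan)
    occupied = n > 0
    mean[occupied] = np.nanmean(stack[:, occupied], axis=0)
    multi = n > 1
    if multi.any():
        sd[multi] = np.nanstd(stack[:, multi], axis=0, ddof=1)
    return RadialProfile(marker=marker, level=level, values=mean, n=n, sd=sd,
                         geometry=geom, ids=ids or {})


def percent_positive(ratios: np.ndarray, model: PositivityModel) -> float:
    """Percentage of a colony's nuclei whose ratio clears the positivity threshold."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("colony has no nuclei")
    return 100.0 * float(np.mean(model.is_positive(r)))
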