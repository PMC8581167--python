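"""Colony identification and quality control.

Nuclei are grouped into colonies by smoothing the union of nucleus masks
with a Gaussian of width comparable to the inter-nucleus spacing and
thresholding the resulting density; connected components of that mask are
colonies. Each
colony is then gated on three rules, in a fixed priority order: proximity to
the image border (incomplete colonies printed at the well edge), area
relative to the nominal 1000-μm disc, and roundness (isoperimetric quotient
4πA/P²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .segmentation import NucleiSegmentation, WellImage

__all__ = ["Colony", "QCThresholds", "colony_roundness",
           "identify_colonies", "qc_filter", "colony_table"]


@dataclass
class Colony:
    """One detected colony with geometry and QC status."""

    colony_id: int
    nucleus_ids: list[int]
    centroid_x_um: float
    centroid_y_um: float
    area_um2: float
    perimeter_um: float
    roundness: float
    border_distance_um: float
    qc_status: str = "qualified"          # qualified | rejected
    rejection_reason: str = "none"        # none | edge | area | roundness

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_ids)


@dataclass
class QCThresholds:
    """Colony QC gate, relative to the nominal printed disc."""

    min_area_frac: float = 0.7
    max_area_frac: float = 1.3
    min_roundness: float = 0.8
    edge_margin_um: float = 10.0
    colony_diameter_um: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.min_area_frac < self.max_area_frac:
            raise ValueError("need 0 < min_area_frac < max_area_frac")
        if not 0 < self.min_roundness <= 1:
            raise ValueError("min_roundness must be in (0, 1]")

    @property
    def nominal_area_um2(self) -> float:
        return math.pi * (self.colony_diameter_um / 2.0) ** 2


def colony_roundness(area: float, perimeter: float) -> float:
    """Isoperimetric quotient 4πA/P², capped at 1 (circle = 1, square ≈ 0.785)."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be > 0")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def identify_colonies(seg: NucleiSegmentation, image: WellImage,
                      smooth_sigma_um: float = 40.0,
                      density_threshold: float = 0.3) -> tuple[list[Colony], np.ndarray, pd.DataFrame]:
    """Group segmented nuclei into colonies.

    The union of nucleus masks is Gaussian-smoothed with a sigma of the
    order of the inter-nucleus spacing and thresholded at
    ``density_threshold`` times the mean smoothed density over nucleus
    pixels; connected components of that mask are colonies. This bridges the
    gaps between neighbouring nuclei while keeping distinct colonies
    (separated by hundreds of μm) apart, and yields a smooth outline whose
    isoperimetric roundness is meaningful. Components that contain no
    nucleus centroid are discarded.

    Returns the colonies (QC not yet applied), the colony label image, and
    the nucleus table with a ``colony_id`` column added (0 = unassigned).
    """
    px = image.pixel_size_um
    table = seg.table.copy()
    if table.empty:
        table["colony_id"] = pd.Series(dtype=int)
        return [], np.zeros(seg.labels.shape, dtype=np.int32), table
    mask = seg.labels > 0
    density = ndimage.gaussian_filter(mask.astype(float), sigma=smooth_sigma_um / px)
    ref = density[mask].mean()
    colony_mask = density > density_threshold * ref
    # light boundary smoothing so the perimeter reflects shape, not pixel noise
    colony_mask = ndimage.gaussian_filter(colony_mask.astype(float), sigma=3.0) > 0.5
    colony_mask = ndimage.binary_fill_holes(colony_mask)
    labels = cc_label(colony_mask).astype(np.int32)

    iy = np.clip(np.round(table["y_um"] / px).astype(int), 0, labels.shape[0] - 1)
    ix = np.clip(np.round(table["x_um"] / px).astype(int), 0, labels.shape[1] - 1)
    table["colony_id"] = labels[iy, ix]

    # drop components with no nuclei, relabel compactly
    occupied = sorted(set(table["colony_id"]) - {0})
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, old in enumerate(occupied, start=1):
        remap[old] = new
    labels = remap[labels]
    table["colony_id"] = remap[table["colony_id"].to_numpy()]

    h, w = labels.shape
    colonies = []
    for rp in regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        border_px = min(minr, minc, h - maxr, w - maxc)
        area = rp.area * px**2
        perim = max(rp.perimeter_crofton, 1e-9) * px
        members = table.loc[table["colony_id"] == rp.label, "nucleus_id"].tolist()
        colonies.append(Colony(
            colony_id=int(rp.label),
            nucleus_ids=members,
            centroid_x_um=rp.centroid[1] * px,
            centroid_y_um=rp.centroid[0] * px,
            area_um2=area,
            perimeter_um=perim,
            roundness=colony_roundness(area, perim),
            border_distance_um=border_px * px,
        ))
    return colonies, labels, table


def qc_filter(colonies: list[Colony], thresholds: QCThresholds) -> list[Colony]:
    """Set QC status on every colony; first failing rule wins (edge > area > roundness)."""
    nominal = thresholds.nominal_area_um2
    out = []
    for c in colonies:
        reason = "none"
        if c.border_distance_um < thresholds.edge_margin_um:
            reason = "edge"
        elif not (thresholds.min_area_frac * nominal <= c.area_um2
                  <= thresholds.max_area_frac * nominal):
            reason = "area"
        elif c.roundness < thresholds.min_roundness:
            reason = "roundness"
        out.append(Colony(**{**c.__dict__,
                             "qc_status": "qualified" if reason == "none" else "rejected",
                             "rejection_reason": reason}))
    return out


def colony_table(colonies: list[Colony], well_id: str = "") -> pd.DataFrame:
    """Flatten colonies into one row per colony for CSV export."""
    return pd.DataFrame([{
        "well": well_id,
        "colony_id": c.colony_id,
        "n_nuclei": c.n_nuclei,
        "centroid_x_um": c.centroid_x_um,
        "centroid_y_um": c.centroid_y_um,
        "area_um2": c.area_um2,
        "perimeter_um": c.perimeter_um,
        "roundness": c.roundness,
        "border_distance_um": c.border_distance_um,
        "qc_status": c.qc_status,
        "rejection_reason": c.rejection_reason,
    } for c in colonies])
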