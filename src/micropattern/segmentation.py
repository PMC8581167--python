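"""Nucleus detection in the DAPI channel and per-nucleus intensity measurement.

The segmenter is deliberately parameter-light: Gaussian smoothing, Otsu
threshold, small-object removal, then a distance-transform watershed to
split touching nuclei. Per-nucleus intensity is the arithmetic mean over
the nucleus mask in every channel; nuclei whose measured DAPI mean is not
positive are dropped (the later DAPI normalisation divides by it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops_table
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = ["WellImage", "SegmentationParams", "NucleiSegmentation",
           "detect_nuclei", "measure_intensities"]

#: Column order of the per-nucleus table produced by this module.
NUCLEUS_COLUMNS = ["nucleus_id", "x_um", "y_um", "area_px", "area_um2"]


@dataclass
class WellImage:
    """One multi-channel well image with physical scale.

    ``pixels`` has shape (n_channels, H, W); ``channel_names`` maps stack
    position to marker name and must include ``"DAPI"``.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    well_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(self.channel_names):
            raise ValueError("pixels must be (n_channels, H, W) matching channel_names")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def markers(self) -> list[str]:
        return [c for c in self.channel_names if c != "DAPI"]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.pixels[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None


@dataclass
class SegmentationParams:
    """Tunables for nucleus detection (lengths in μm)."""

    smooth_sigma_um: float = 2.0
    expected_nucleus_radius_um: float = 6.0
    min_area_frac: float = 0.25   # of expected nucleus area
    peak_min_distance_um: float = 8.0


@dataclass
class NucleiSegmentation:
    """Label image plus the per-nucleus geometry table.

    Label ``k`` in ``labels`` corresponds to the row with ``nucleus_id == k``.
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size_um: float = field(default=1.0)

    def __len__(self) -> int:
        return len(self.table)


def detect_nuclei(image: WellImage, params: SegmentationParams | None = None) -> NucleiSegmentation:
    """Segment nuclei in the DAPI channel.

    Returns centroids (μm) and pixel areas; intensity measurement and colony
    assignment happen downstream. A blank image yields an empty table.
    """
    params = params or SegmentationParams()
    if "DAPI" not in image.channel_names:
        raise ValueError("image has no DAPI channel; cannot segment nuclei")
    dapi = image.channel("DAPI").astype(float)
    px = image.pixel_size_um
    empty = NucleiSegmentation(
        labels=np.zeros(dapi.shape, dtype=np.int32),
        table=pd.DataFrame(columns=NUCLEUS_COLUMNS),
        pixel_size_um=px,
    )
    if not np.any(dapi > 0):
        return empty
    smoothed = gaussian(dapi, sigma=params.smooth_sigma_um / px, preserve_range=True)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    min_area_px = params.min_area_frac * math.pi * (params.expected_nucleus_radius_um / px) ** 2
    mask = remove_small_objects(mask, max_size=max(1, int(min_area_px)))
    if not mask.any():
        return empty

    distance = ndimage.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(params.peak_min_distance_um / px)))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask).astype(np.int32)

    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    table = pd.DataFrame({
        "nucleus_id": props["label"],
        "x_um": props["centroid-1"] * px,
        "y_um": props["centroid-0"] * px,
        "area_px": props["area"].astype(int),
        "area_um2": props["area"] * px**2,
    })
    return NucleiSegmentation(labels=labels, table=table, pixel_size_um=px)


def measure_intensities(image: WellImage, seg: NucleiSegmentation) -> pd.DataFrame:
    """Mean intensity per nucleus in every channel.

    Adds one column per channel (lower-cased ``dapi`` plus each marker name)
    to the segmentation table. Nuclei with non-positive DAPI mean are dropped
    and logged: the DAPI-normalisation divide downstream must be defined.
    """
    if seg.labels.shape != image.pixels.shape[1:]:
        raise ValueError("segmentation labels do not match image dimensions")
    table = seg.table.copy()
    if table.empty:
        for name in image.channel_names:
            table[name.lower() if name == "DAPI" else name] = pd.Series(dtype=float)
        return table
    ids = table["nucleus_id"].to_numpy()
    for name in image.channel_names:
        means = ndimage.mean(image.channel(name).astype(float), labels=seg.labels, index=ids)
        table[name.lower() if name == "DAPI" else name] = means
    n0 = len(table)
    table = table[table["dapi"] > 0].reset_index(drop=True)
    if len(table) < n0:
        logger.warning("dropped %d nuclei with non-positive DAPI mean", n0 - len(table))
    return table
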