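"""Plate-layout configuration and multi-channel TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .segmentation import WellImage

__all__ = ["WellInfo", "PlateLayout", "read_well_image", "write_well_image"]


@dataclass(frozen=True)
class WellInfo:
    line: str
    donor: str = ""
    experiment: str = "exp1"
    replicate: str = "rep1"


@dataclass
class PlateLayout:
    """Maps wells to (line, donor, experiment, replicate) and channels to markers.

    ``channels`` maps the stack index of each image plane to a marker name
    and must include DAPI. ``control_line`` designates the line used as the
    reference for radial-outlier KS tests.
    """

    wells: dict[str, WellInfo]
    channels: dict[int, str]
    pixel_size_um: float
    control_line: str = ""

    def __post_init__(self) -> None:
        if "DAPI" not in self.channels.values():
            raise ValueError("channel map must include DAPI")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.control_line and self.control_line not in {w.line for w in self.wells.values()}:
            raise ValueError(f"control line {self.control_line!r} not present in layout")

    @property
    def channel_names(self) -> list[str]:
        return [self.channels[i] for i in sorted(self.channels)]

    @property
    def lines(self) -> list[str]:
        return sorted({w.line for w in self.wells.values()})

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        wells = {wid: WellInfo(**info) for wid, info in raw["wells"].items()}
        channels = {int(k): v for k, v in raw["channels"].items()}
        return cls(wells=wells, channels=channels,
                   pixel_size_um=float(raw["pixel_size_um"]),
                   control_line=raw.get("control_line", ""))

    def to_yaml(self, path) -> None:
        raw = {
            "pixel_size_um": self.pixel_size_um,
            "control_line": self.control_line,
            "channels": {int(k): v for k, v in self.channels.items()},
            "wells": {wid: {"line": w.line, "donor": w.donor,
                            "experiment": w.experiment, "replicate": w.replicate}
                      for wid, w in self.wells.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def write_well_image(image: WellImage, path, dtype: str = "float32") -> None:
    """Write a well image as a multi-page TIFF (float32, or uint16 for export)."""
    path = Path(path)
    if dtype == "uint16":
        scale = 65535.0 / max(float(image.pixels.max()), 1e-9)
        data = np.clip(image.pixels * scale, 0, 65535).astype(np.uint16)
    else:
        data = image.pixels.astype(np.float32)
    tifffile.imwrite(path, data, metadata={
        "axes": "CYX",
        "channels": image.channel_names,
        "pixel_size_um": image.pixel_size_um,
        "well_id": image.well_id,
    })


def read_well_image(path, layout: PlateLayout, well_id: str | None = None) -> WellImage:
    """Read a multi-channel TIFF and attach marker names and pixel scale."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    names = layout.channel_names
    if data.shape[0] != len(names):
        raise ValueError(
            f"{path.name}: image has {data.shape[0]} channels but layout maps {len(names)}")
    wid = well_id if well_id is not None else path.stem
    if wid not in layout.wells:
        raise KeyError(f"well {wid!r} not present in plate layout")
    return WellImage(pixels=np.asarray(data, dtype=np.float32), channel_names=list(names),
                     pixel_size_um=layout.pixel_size_um, well_id=wid)
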