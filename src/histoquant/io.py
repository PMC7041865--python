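"""Image containers and TIFF/YAML serialization.

A :class:`TissueImage` is a named set of co-registered 2-D channels (one per
stain) with a physical pixel size.  On disk an image is a multi-page TIFF
(one page per channel, 16-bit) plus a YAML sidecar that names the channels,
records acquisition metadata and the per-channel intensity scale factor used
for the 16-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

__all__ = ["TissueImage", "write_tissue_image", "read_tissue_image"]

_MAX_U16 = 65535


@dataclass
class TissueImage:
    """Multichannel 2-D fluorescence image of one tissue section.

    Parameters
    ----------
    channels
        Mapping of stain name (e.g. ``"DAPI"``, ``"Ki67"``, ``"uptake"``) to a
        2-D non-negative float array.  All channels must share dimensions.
    pixel_size_um
        Physical size of one pixel in microns; must be positive.
    channel_meta
        Optional free-text acquisition metadata per channel (stain, exposure,
        filter set ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    channel_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channels:
            raise ValueError("TissueImage requires at least one channel")
        shapes = {np.asarray(ch).shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share dimensions, got {shapes}")
        shape = shapes.pop()
        if len(shape) != 2 or 0 in shape:
            raise ValueError(f"channels must be non-empty 2-D rasters, got shape {shape}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]

    def channel_names(self) -> list[str]:
        return list(self.channels)


def write_tissue_image(img: TissueImage, directory: str | Path, stem: str = "image") -> Path:
    """Write ``img`` as ``<stem>.tif`` (multi-page, uint16) + ``<stem>.yaml``.

    Intensities are scaled per channel to the 16-bit range; the scale factor is
    stored in the sidecar so readers can restore physical intensity units (to
    within one quantization step).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif_path = directory / f"{stem}.tif"
    meta: dict = {
        "pixel_size_um": float(img.pixel_size_um),
        "channels": [],
    }
    pages = []
    for name, ch in img.channels.items():
        peak = float(ch.max())
        scale = peak / _MAX_U16 if peak > 0 else 1.0
        pages.append(np.round(ch / scale).astype(np.uint16))
        entry = {"name": name, "scale": scale}
        entry.update(img.channel_meta.get(name, {}))
        meta["channels"].append(entry)
    tifffile.imwrite(tif_path, np.stack(pages), photometric="minisblack")
    with open(directory / f"{stem}.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return tif_path


def read_tissue_image(directory: str | Path, stem: str = "image") -> TissueImage:
    """Read an image written by :func:`write_tissue_image`."""
    directory = Path(directory)
    with open(directory / f"{stem}.yaml") as fh:
        meta = yaml.safe_load(fh)
    stack = tifffile.imread(directory / f"{stem}.tif")
    if stack.ndim == 2:
        stack = stack[None]
    channels: dict[str, np.ndarray] = {}
    channel_meta: dict[str, dict] = {}
    for page, entry in zip(stack, meta["channels"]):
        name = entry["name"]
        channels[name] = page.astype(float) * float(entry["scale"])
        channel_meta[name] = {
            k: v for k, v in entry.items() if k not in ("name", "scale")
        }
    return TissueImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_meta=channel_meta,
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label raster as 16-bit TIFF (lossless up to 65535 labels)."""
    labels = np.asarray(labels)
    if labels.max() > _MAX_U16:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)
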