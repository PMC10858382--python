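"""File I/O: rasters (PNG/TIFF), YAML sidecars, and CSV tables.

All rasters are row-major with 0-based pixel indices and pixel-center
coordinates in micrometers; physical units travel in YAML sidecars or CSV
columns, never implicitly.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .compartments import CompartmentMaskSet
from .registration import RigidScaleTransform

__all__ = [
    "write_histology_png", "read_histology_png",
    "write_float_tiff", "read_float_tiff",
    "write_mask_tiff", "read_mask_tiff",
    "write_maskset_tiff", "read_maskset_tiff",
    "write_yaml", "read_yaml",
    "write_transform_yaml", "read_transform_yaml",
]


def write_histology_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_histology_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))[..., :3]


def write_float_tiff(path, arr: np.ndarray, units: str | None = None) -> None:
    desc = f"units={units}" if units else None
    tifffile.imwrite(Path(path), np.asarray(arr, dtype=np.float32), description=desc)


def read_float_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.uint8)


def write_maskset_tiff(path, maskset: CompartmentMaskSet) -> None:
    """Multi-page 8-bit TIFF, page order: background, tissue_core, bone_core, interface."""
    pages = np.stack([
        maskset.background, maskset.tissue_core, maskset.bone_core, maskset.interface,
    ]).astype(np.uint8)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def read_maskset_tiff(path, pitch_um: float,
                      interface_halfwidth_um: float = 50.0) -> CompartmentMaskSet:
    pages = tifffile.imread(Path(path)).astype(bool)
    return CompartmentMaskSet(
        background=pages[0], tissue_core=pages[1], bone_core=pages[2],
        interface=pages[3], pitch_um=pitch_um,
        interface_halfwidth_um=interface_halfwidth_um,
    )


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_transform_yaml(path, t: RigidScaleTransform) -> None:
    write_yaml(path, t.to_dict())


def read_transform_yaml(path) -> RigidScaleTransform:
    return RigidScaleTransform.from_dict(read_yaml(path))
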