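"""Analysis compartments: bone core, soft-tissue core, and the interface.

Ra-223 is surface-seeking, so the analysis distinguishes a bone-tissue
interface band extending a fixed physical half-width (default 50 um) into
each compartment from the remaining "core" bone and soft tissue.  The band
is defined at histology resolution, where the 50-um figure spans several
pixels, and only then downsampled to the coarser DAR grid so it is not
quantized away by the ~43-um DAR pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import resample_labels
from .segmentation import (
    LABEL_BACKGROUND,
    LABEL_BONE,
    LABEL_SOFT_TISSUE,
    CompartmentLabelMap,
)

__all__ = ["CompartmentMaskSet", "build_interface", "compartment_of",
           "maskset_to_dar", "compartment_areas"]

# compact label codes used when a mask set travels as a single raster
CODE = {"background": 0, "tissue_core": 1, "bone_core": 2, "interface": 3}


@dataclass
class CompartmentMaskSet:
    """Disjoint cover of the raster by the four analysis compartments."""

    bone_core: np.ndarray
    tissue_core: np.ndarray
    interface: np.ndarray
    background: np.ndarray
    pitch_um: float
    interface_halfwidth_um: float = 50.0

    def __post_init__(self):
        total = (self.bone_core.astype(int) + self.tissue_core.astype(int)
                 + self.interface.astype(int) + self.background.astype(int))
        if not (total == 1).all():
            raise ValueError("compartment masks must be a disjoint cover of the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bone_core.shape

    def coded(self) -> np.ndarray:
        """Single-raster encoding using :data:`CODE`."""
        out = np.zeros(self.shape, dtype=np.uint8)
        out[self.tissue_core] = CODE["tissue_core"]
        out[self.bone_core] = CODE["bone_core"]
        out[self.interface] = CODE["interface"]
        return out

    @classmethod
    def from_coded(cls, coded: np.ndarray, pitch_um: float,
                   interface_halfwidth_um: float = 50.0) -> "CompartmentMaskSet":
        return cls(
            bone_core=coded == CODE["bone_core"],
            tissue_core=coded == CODE["tissue_core"],
            interface=coded == CODE["interface"],
            background=coded == CODE["background"],
            pitch_um=pitch_um,
            interface_halfwidth_um=interface_halfwidth_um,
        )


def build_interface(labelmap: CompartmentLabelMap,
                    halfwidth_um: float = 50.0) -> CompartmentMaskSet:
    """Split bone and tissue into cores and a boundary band.

    A bone (tissue) pixel joins the interface iff its center lies within
    ``halfwidth_um`` of the nearest tissue (bone) pixel center — i.e. the
    band extends the half-width into each compartment from the boundary.
    With only one of the two classes present the interface is empty.
    """
    labels = np.asarray(labelmap.labels)
    if not np.isin(labels, [LABEL_BACKGROUND, LABEL_SOFT_TISSUE, LABEL_BONE]).all():
        raise ValueError("label codes must be in {0, 1, 2}")
    bone = labels == LABEL_BONE
    tissue = labels == LABEL_SOFT_TISSUE
    pitch = labelmap.pitch_um
    if bone.any() and tissue.any():
        d_to_bone = ndimage.distance_transform_edt(~bone, sampling=pitch)
        d_to_tissue = ndimage.distance_transform_edt(~tissue, sampling=pitch)
        interface = (bone & (d_to_tissue <= halfwidth_um)) | (tissue & (d_to_bone <= halfwidth_um))
    else:
        interface = np.zeros_like(bone)
    return CompartmentMaskSet(
        bone_core=bone & ~interface,
        tissue_core=tissue & ~interface,
        interface=interface,
        background=~(bone | tissue),
        pitch_um=pitch,
        interface_halfwidth_um=halfwidth_um,
    )


def compartment_of(pixel: tuple[int, int], maskset: CompartmentMaskSet) -> str:
    """Name of the unique compartment containing ``pixel`` (row, col)."""
    r, c = pixel
    for name in ("bone_core", "tissue_core", "interface", "background"):
        if getattr(maskset, name)[r, c]:
            return name
    raise IndexError(f"pixel {pixel} outside raster")  # pragma: no cover


def maskset_to_dar(maskset: CompartmentMaskSet, dar_pitch_um: float) -> CompartmentMaskSet:
    """Downsample a mask set to the DAR pitch by occupancy majority.

    Each DAR pixel takes the compartment covering the largest fraction of
    its footprint (ties to the lower code, background lowest).
    """
    if dar_pitch_um < maskset.pitch_um:
        raise ValueError("dar_pitch_um must be >= the mask set pitch")
    coded = resample_labels(maskset.coded(), dar_pitch_um / maskset.pitch_um)
    return CompartmentMaskSet.from_coded(coded, dar_pitch_um,
                                         maskset.interface_halfwidth_um)


def compartment_areas(maskset: CompartmentMaskSet) -> pd.DataFrame:
    """Pixel counts and physical areas (mm^2) per compartment."""
    px_area_mm2 = (maskset.pitch_um * 1e-3) ** 2
    rows = []
    for name in ("background", "tissue_core", "bone_core", "interface"):
        n = int(getattr(maskset, name).sum())
        rows.append({"compartment": name, "n_pixels": n, "area_mm2": n * px_area_mm2})
    return pd.DataFrame(rows)
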