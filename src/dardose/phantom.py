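"""Synthetic bone-metastasis biopsy phantom.

Generates everything the real acquisition would provide — an H&E-like
histology raster, a storage-phosphor autoradiograph (DAR) in digital light
units with a co-imaged activity-standard strip, and the acquisition
metadata — together with the ground truth (compartment masks, per-voxel
activity, inter-modality transform) that patient data cannot supply.

The phantom emulates the salient physics of a Ra-223 biopsy section:

* an elliptical ~2-mm biopsy core of trabecular bone and soft tissue, the
  bone drawn as a thresholded low-pass-filtered Gaussian random field with a
  controllable volume fraction and correlation length;
* surface-seeking activity: concentration peaks at the bone-tissue boundary
  and decays exponentially with distance into either compartment, over a low
  uniform soft-tissue background, with a few focal hot spots;
* storage-phosphor image formation: expected decays = activity x exposure,
  Gaussian point-spread blur, Poisson counting statistics, and a linear
  DLU-per-decay gain;
* a known similarity misalignment between the DAR frame and the histology
  frame, and a standards strip rendered through the same imaging chain.

All randomness derives from ``PhantomConfig.seed``; identical configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import block_resample
from .registration import RigidScaleTransform, apply_transform

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "SECTION_THICKNESS_UM",
    "generate_masks",
    "generate_activity_map",
    "render_histology",
    "render_autoradiograph",
    "make_phantom",
]

#: Cryosection thickness (um); fixed by the sectioning protocol.
SECTION_THICKNESS_UM = 8.0

# H&E-like rendering means (8-bit RGB): pale eosin bone, hematoxylin-dense
# soft tissue, near-white slide background.
CLASS_COLORS = {
    0: (245.0, 245.0, 245.0),  # background
    1: (150.0, 95.0, 160.0),   # soft tissue
    2: (230.0, 185.0, 190.0),  # bone
}


@dataclass
class PhantomConfig:
    """Generation parameters; defaults emulate the study's acquisition."""

    image_height_px: int = 896
    image_width_px: int = 384
    hist_pitch_um: float = 8.0
    dar_pitch_um: float = 43.2
    bone_volume_fraction: float = 0.3
    correlation_length_um: float = 150.0
    surface_activity_conc: float = 25.0     # Bq/mm^3 at the interface
    decay_length_um: float = 50.0
    tissue_background_conc: float = 0.3     # Bq/mm^3; soft tissue is a low-activity
                                            # background (blood ~0.005-0.013 Bq/mm^3 at 24 h)
    bone_background_conc: float = 1.5       # Bq/mm^3; diffuse uptake in mineralized bone,
                                            # an order of magnitude below the surface peak
    n_hotspots: int = 3
    hotspot_gain: float = 3.0
    hotspot_radius_um: float = 100.0
    psf_sigma_um: float = 17.0              # ~40 um FWHM readout resolution
    gain_dlu_per_decay: float = 1.0
    exposure_s: float = 86400.0
    misalignment: RigidScaleTransform | None = None
    standard_activities_bq: tuple[float, ...] = (2e-4, 5e-4, 1e-3, 2e-3)  # Bq/voxel
    core_axes_frac: tuple[float, float] = (0.45, 0.32)
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px < 16 or self.image_width_px < 16:
            raise ValueError("image must be at least 16 px per side")
        if not 0.0 <= self.bone_volume_fraction < 1.0:
            raise ValueError("bone_volume_fraction must be in [0, 1)")
        for name in ("hist_pitch_um", "dar_pitch_um", "exposure_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("surface_activity_conc", "decay_length_um", "tissue_background_conc",
                     "bone_background_conc",
                     "psf_sigma_um", "gain_dlu_per_decay", "correlation_length_um",
                     "hotspot_gain", "hotspot_radius_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(a < 0 for a in self.standard_activities_bq):
            raise ValueError("standard activities must be >= 0")
        if self.misalignment is None:
            c = ((self.image_height_px * self.hist_pitch_um / self.dar_pitch_um) / 2.0,
                 (self.image_width_px * self.hist_pitch_um / self.dar_pitch_um) / 2.0)
            self.misalignment = RigidScaleTransform(
                scale=1.02, rotation_deg=5.0, translation=(6.0, -3.0), center=c)

    def _rng(self, stage: int) -> np.random.Generator:
        # independent, reproducible stream per generation stage
        return np.random.default_rng([stage, self.seed])

    @property
    def hist_pixel_volume_mm3(self) -> float:
        return self.hist_pitch_um ** 2 * SECTION_THICKNESS_UM * 1e-9

    @property
    def dar_voxel_volume_mm3(self) -> float:
        return self.dar_pitch_um ** 2 * SECTION_THICKNESS_UM * 1e-9


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic section."""

    bone_mask: np.ndarray
    tissue_mask: np.ndarray
    activity_map_true: np.ndarray           # Bq per DAR voxel at biopsy time
    transform_true: RigidScaleTransform     # maps histology-aligned DAR frame -> acquired DAR frame
    standards_map: np.ndarray               # DLU raster of the standards strip
    standard_activities_bq: tuple[float, ...]
    standard_slices: list[tuple[slice, slice]]


def _core_mask(cfg: PhantomConfig) -> np.ndarray:
    H, W = cfg.image_height_px, cfg.image_width_px
    rr, cc = np.mgrid[0:H, 0:W]
    a, b = cfg.core_axes_frac[0] * H, cfg.core_axes_frac[1] * W
    return ((rr - H / 2) / a) ** 2 + ((cc - W / 2) / b) ** 2 <= 1.0


def generate_masks(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Trabecular bone and soft-tissue masks at histology pitch.

    Bone is a low-pass-filtered Gaussian random field thresholded at the
    quantile that yields ``bone_volume_fraction`` inside the elliptical core;
    soft tissue is the remainder of the core.
    """
    core = _core_mask(cfg)
    if cfg.bone_volume_fraction == 0.0:
        return np.zeros_like(core), core
    rng = cfg._rng(1)
    noise = rng.standard_normal(core.shape)
    sigma_px = cfg.correlation_length_um / cfg.hist_pitch_um
    fld = ndimage.gaussian_filter(noise, sigma=sigma_px)
    thr = np.quantile(fld[core], 1.0 - cfg.bone_volume_fraction)
    bone = core & (fld > thr)
    tissue = core & ~bone
    return bone, tissue


def _boundary_distance_um(bone: np.ndarray, tissue: np.ndarray, pitch_um: float) -> np.ndarray:
    """Distance (um) of each pixel to the bone-tissue boundary.

    The boundary is the set of bone or tissue pixels 8-adjacent to the other
    class; boundary pixels are at distance 0.
    """
    if not bone.any() or not tissue.any():
        return np.full(bone.shape, np.inf)
    st = np.ones((3, 3), bool)
    border = (bone & ndimage.binary_dilation(tissue, st)) | (tissue & ndimage.binary_dilation(bone, st))
    return ndimage.distance_transform_edt(~border, sampling=pitch_um)


def generate_activity_map(cfg: PhantomConfig, bone_mask: np.ndarray,
                          tissue_mask: np.ndarray) -> np.ndarray:
    """True Ra-223 activity per DAR voxel (Bq) at biopsy time.

    Concentration is ``surface_activity_conc * exp(-d / decay_length_um)``
    at distance ``d`` from the bone-tissue boundary within bone and tissue,
    plus a uniform diffuse background in each compartment (higher in
    mineralized bone than in soft tissue, emulating the bone-seeking ion);
    a few interface patches are multiplied by ``hotspot_gain``.  Converted to Bq per histology pixel and
    block-summed onto the DAR grid, conserving total activity.
    """
    bq_per_hist_px = _activity_hist_bq(cfg, bone_mask, tissue_mask)
    ratio = cfg.dar_pitch_um / cfg.hist_pitch_um
    return block_resample(bq_per_hist_px, ratio, reduce="sum")


def _activity_hist_bq(cfg: PhantomConfig, bone_mask: np.ndarray,
                      tissue_mask: np.ndarray) -> np.ndarray:
    """Bq per histology pixel at biopsy time (fine-grid activity field)."""
    if bone_mask.shape != tissue_mask.shape:
        raise ValueError("bone and tissue masks must share a shape")
    section = bone_mask | tissue_mask
    d = _boundary_distance_um(bone_mask, tissue_mask, cfg.hist_pitch_um)
    with np.errstate(over="ignore"):
        conc = np.where(section, cfg.surface_activity_conc * np.exp(-d / cfg.decay_length_um), 0.0)
    conc[tissue_mask] += cfg.tissue_background_conc
    conc[bone_mask] += cfg.bone_background_conc

    if cfg.n_hotspots > 0 and np.isfinite(d).any():
        border = np.argwhere(d == 0)
        if border.size:
            rng = cfg._rng(2)
            picks = border[rng.choice(len(border), size=min(cfg.n_hotspots, len(border)),
                                      replace=False)]
            rr, cc = np.mgrid[0:conc.shape[0], 0:conc.shape[1]]
            r_px = cfg.hotspot_radius_um / cfg.hist_pitch_um
            for (pr, pc) in picks:
                spot = (rr - pr) ** 2 + (cc - pc) ** 2 <= r_px ** 2
                conc[spot & section] *= cfg.hotspot_gain

    return conc * cfg.hist_pixel_volume_mm3


def render_histology(cfg: PhantomConfig, bone_mask: np.ndarray, tissue_mask: np.ndarray,
                     noise_sigma: float = 8.0) -> np.ndarray:
    """H&E-like 8-bit RGB rendering of the section (class colors + noise)."""
    if bone_mask.shape != tissue_mask.shape:
        raise ValueError("bone and tissue masks must share a shape")
    labels = np.zeros(bone_mask.shape, dtype=int)
    labels[tissue_mask] = 1
    labels[bone_mask] = 2
    rgb = np.empty(labels.shape + (3,), dtype=float)
    for code, color in CLASS_COLORS.items():
        rgb[labels == code] = color
    if noise_sigma > 0:
        rng = cfg._rng(3)
        rgb = rgb + rng.normal(0.0, noise_sigma, size=rgb.shape)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _image_chain(cfg: PhantomConfig, expected_decays: np.ndarray,
                 rng: np.random.Generator | None) -> np.ndarray:
    """PSF blur -> Poisson counting -> DLU gain."""
    sigma_px = cfg.psf_sigma_um / cfg.dar_pitch_um
    exp_blur = ndimage.gaussian_filter(expected_decays, sigma=sigma_px) if sigma_px > 0 \
        else expected_decays
    counts = rng.poisson(exp_blur).astype(float) if rng is not None else exp_blur
    return counts * cfg.gain_dlu_per_decay


def render_autoradiograph(cfg: PhantomConfig, activity_map_true: np.ndarray,
                          transform_true: RigidScaleTransform | None = None,
                          poisson: bool = True,
                          standard_patch_px: int = 12,
                          activity_hist_bq: np.ndarray | None = None,
                          ) -> tuple[np.ndarray, np.ndarray, list[tuple[slice, slice]]]:
    """Storage-phosphor DLU image of the section plus the standards strip.

    Expected decays per voxel are ``activity x exposure_s`` (exposure is far
    shorter than the Ra-223 half-life, so activity is treated as constant).
    The inverse of ``transform_true`` is applied so the acquired DAR frame is
    misaligned from histology.  Standards are uniform patches of known
    per-voxel activity, one rectangle per entry of
    ``standard_activities_bq``, pushed through the same PSF/noise/gain chain.

    When the fine-grid activity field ``activity_hist_bq`` (Bq per histology
    pixel) is supplied, the misalignment is applied at histology pitch and
    the warped field integrated onto the detector voxels — the faithful
    image-formation order; warping the already voxel-aggregated map instead
    smears the thin interface band by the width of the interpolation kernel.

    Returns ``(dar_image, standards_map, standard_slices)``.
    """
    act = np.asarray(activity_map_true, dtype=float)
    if (act < 0).any():
        raise ValueError("activity map must be non-negative")
    if transform_true is None:
        transform_true = cfg.misalignment
    if activity_hist_bq is not None:
        ratio = cfg.dar_pitch_um / cfg.hist_pitch_um
        t_hist = RigidScaleTransform(
            scale=transform_true.scale, rotation_deg=transform_true.rotation_deg,
            translation=tuple(np.asarray(transform_true.translation) * ratio),
            center=tuple(np.asarray(transform_true.center) * ratio))
        warped = apply_transform(np.asarray(activity_hist_bq, float) * cfg.exposure_s,
                                 t_hist.inverse(), "bilinear")
        misaligned = block_resample(warped, ratio, reduce="sum")
    else:
        expected = act * cfg.exposure_s
        misaligned = apply_transform(expected, transform_true.inverse(), "bilinear")
    rng = cfg._rng(4) if poisson else None
    dar = _image_chain(cfg, misaligned, rng)

    # standards strip: one patch per known activity, margins of 4 px
    n = len(cfg.standard_activities_bq)
    m, p = 4, standard_patch_px
    strip = np.zeros((n * (p + m) + m, p + 2 * m))
    slices = []
    for i, a in enumerate(cfg.standard_activities_bq):
        sl = (slice(m + i * (p + m), m + i * (p + m) + p), slice(m, m + p))
        strip[sl] = a * cfg.exposure_s
        slices.append(sl)
    rng_std = cfg._rng(5) if poisson else None
    standards = _image_chain(cfg, strip, rng_std)
    return dar, standards, slices


def make_phantom(cfg: PhantomConfig, poisson: bool = True,
                 noise_sigma: float = 8.0) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Generate one full synthetic section.

    Returns ``(histology_rgb, dar_image, truth)``.
    """
    bone, tissue = generate_masks(cfg)
    bq_hist = _activity_hist_bq(cfg, bone, tissue)
    ratio = cfg.dar_pitch_um / cfg.hist_pitch_um
    act = block_resample(bq_hist, ratio, reduce="sum")
    rgb = render_histology(cfg, bone, tissue, noise_sigma=noise_sigma)
    dar, standards, slices = render_autoradiograph(cfg, act, poisson=poisson,
                                                   activity_hist_bq=bq_hist)
    truth = PhantomTruth(
        bone_mask=bone, tissue_mask=tissue, activity_map_true=act,
        transform_true=cfg.misalignment, standards_map=standards,
        standard_activities_bq=cfg.standard_activities_bq, standard_slices=slices,
    )
    return rgb, dar, truth
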