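"""DAR calibration, Ra-223 activity quantification, and MIRD voxel dosimetry.

The storage-phosphor readout is an arbitrary linear unit (DLU); co-imaged
activity standards anchor it to becquerels via an ordinary least-squares
calibration.  Calibrated per-voxel activity is decay-corrected to biopsy
time, integrated to infinity under physical Ra-223 decay (the isotope and
its alpha-emitting daughters Rn-219, Po-215 and Bi-211 are assumed fixed in
bone, i.e. no biological clearance), and converted to absorbed dose with
the MIRD voxel formalism

    D = A_tilde * Delta * phi / mass

where ``Delta`` is the summed mean alpha energy per Ra-223 transformation
of the chain in secular equilibrium, ``phi = 1`` (all alpha energy deposited
in the emitting voxel — the maximally local assumption), and the voxel mass
follows from the 43.2 x 43.2 x 8 um voxel and the compartment density
(bone 1.92 g/cm^3; soft tissue and interface 1.03 g/cm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy import stats

from .compartments import CompartmentMaskSet
from .phantom import SECTION_THICKNESS_UM

__all__ = [
    "Nuclide",
    "DecayChainData",
    "RA223_CHAIN",
    "DosimetryConstants",
    "CalibrationCurve",
    "ActivityMap",
    "DoseMap",
    "delta_constant",
    "fit_calibration",
    "dlu_to_activity",
    "cumulated_activity",
    "voxel_mass",
    "compute_dose_map",
]

MEV_TO_J = 1.602177e-13
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class Nuclide:
    half_life_s: float
    mean_alpha_energy_MeV: float  # intensity-weighted, per transformation

    def __post_init__(self):
        if self.half_life_s <= 0 or self.mean_alpha_energy_MeV <= 0:
            raise ValueError("half-life and alpha energy must be > 0")


@dataclass(frozen=True)
class DecayChainData:
    """Ra-223 alpha chain in secular equilibrium.

    One transformation of each daughter accompanies each Ra-223 decay, so
    the chain's alpha energy is counted once per parent decay via Delta.
    Mean alpha energies per transformation are intensity-weighted ICRP
    Publication 107 values; the Bi-211 entry is branch-weighted over its
    alpha decay to Tl-207 (99.7%) and the beta branch through Po-211.
    """

    nuclides: dict[str, Nuclide] = field(default_factory=lambda: dict(_ICRP107_CHAIN))

    @property
    def lambda_ra_per_s(self) -> float:
        return np.log(2.0) / self.nuclides["Ra-223"].half_life_s


_ICRP107_CHAIN = {
    "Ra-223": Nuclide(half_life_s=11.43 * SECONDS_PER_DAY, mean_alpha_energy_MeV=5.667),
    "Rn-219": Nuclide(half_life_s=3.96, mean_alpha_energy_MeV=6.750),
    "Po-215": Nuclide(half_life_s=1.781e-3, mean_alpha_energy_MeV=7.386),
    "Bi-211": Nuclide(half_life_s=128.4, mean_alpha_energy_MeV=6.568),
}

RA223_CHAIN = DecayChainData()

_REQUIRED_NUCLIDES = ("Ra-223", "Rn-219", "Po-215", "Bi-211")


@dataclass(frozen=True)
class DosimetryConstants:
    """Voxel-dosimetry constants (MIRD local-deposition model)."""

    delta_J_per_Bq_s: float | None = None  # None -> computed from the chain
    phi: float = 1.0
    rho_bone_g_cm3: float = 1.92
    rho_soft_g_cm3: float = 1.03  # soft tissue and interface
    voxel_um: tuple[float, float, float] = (43.2, 43.2, SECTION_THICKNESS_UM)

    def __post_init__(self):
        if not 0 < self.phi <= 1:
            raise ValueError("phi must be in (0, 1]")
        if self.rho_bone_g_cm3 <= 0 or self.rho_soft_g_cm3 <= 0:
            raise ValueError("densities must be > 0")

    @property
    def voxel_volume_cm3(self) -> float:
        x, y, z = self.voxel_um
        return x * y * z * 1e-12

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_volume_cm3 * 1e3


def delta_constant(chain: DecayChainData = RA223_CHAIN) -> float:
    """Mean alpha energy per Ra-223 transformation, J/(Bq*s).

    Sums the intensity-weighted mean alpha energies of the full chain (one
    transformation of each member per parent decay under secular
    equilibrium) and converts MeV to joules.
    """
    missing = [n for n in _REQUIRED_NUCLIDES if n not in chain.nuclides]
    if missing:
        raise ValueError(f"decay chain is missing nuclides: {missing}")
    total_mev = sum(chain.nuclides[n].mean_alpha_energy_MeV for n in _REQUIRED_NUCLIDES)
    return total_mev * MEV_TO_J


@dataclass
class CalibrationCurve:
    """Linear DLU-vs-activity calibration from co-imaged standards.

    ``readout_time`` is the decay-correction reference instant of the DAR
    signal — the start of the exposure (standards share the exposure, so
    exposure-duration effects cancel in the ratio).
    """

    slope_dlu_per_bq: float
    intercept_dlu: float
    r_squared: float
    exposure_s: float
    readout_time: datetime | None = None
    biopsy_time: datetime | None = None


@dataclass
class ActivityMap:
    """Per-voxel Ra-223 activity (Bq) at biopsy time on the DAR grid."""

    bq_per_voxel: np.ndarray
    limit_of_detection_bq: float
    n_floored: int = 0


@dataclass
class DoseMap:
    """Per-voxel absorbed dose (Gy) from the cumulated alpha-chain emissions."""

    gy_per_voxel: np.ndarray
    maskset: CompartmentMaskSet


def fit_calibration(standards: list[tuple[float, float]], exposure_s: float,
                    readout_time: datetime | None = None,
                    biopsy_time: datetime | None = None) -> CalibrationCurve:
    """OLS fit of mean standard DLU against known activity (Bq).

    ``standards`` are ``(known_bq, mean_dlu)`` pairs.  Requires >= 3
    standards and a positive fitted slope; a standards set spanning less
    than a decade, or an intercept above 5% of the maximum DLU, draws a
    warning.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    bq = np.array([s[0] for s in standards], dtype=float)
    dlu = np.array([s[1] for s in standards], dtype=float)
    pos = bq[bq > 0]
    if pos.size and pos.max() / pos.min() < 10.0:
        warnings.warn("calibration standards span less than one decade", stacklevel=2)
    fit = stats.linregress(bq, dlu)
    if fit.slope <= 0:
        raise ValueError("calibration slope is non-positive; standards are unusable")
    if abs(fit.intercept) > 0.05 * dlu.max():
        warnings.warn("calibration intercept exceeds 5% of the maximum DLU", stacklevel=2)
    return CalibrationCurve(
        slope_dlu_per_bq=float(fit.slope),
        intercept_dlu=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        exposure_s=exposure_s,
        readout_time=readout_time,
        biopsy_time=biopsy_time,
    )


def dlu_to_activity(dar_image: np.ndarray, cal: CalibrationCurve,
                    chain: DecayChainData = RA223_CHAIN,
                    background_mask: np.ndarray | None = None) -> ActivityMap:
    """Invert the calibration and decay-correct to biopsy time.

    Per voxel: ``A_ref = (DLU - intercept) / slope`` at the exposure-start
    reference, then ``A_biopsy = A_ref * exp(lambda_Ra * dt)`` with
    ``dt = readout reference - biopsy time >= 0``.  Negative calibrated
    activities (background noise) are floored at zero and counted.  The
    detection limit is three standard deviations of the background voxels
    passed through the same curve; without an explicit ``background_mask``
    the dimmest quartile of voxels stands in for background.
    """
    dar = np.asarray(dar_image, dtype=float)
    a_ref = (dar - cal.intercept_dlu) / cal.slope_dlu_per_bq
    if cal.readout_time is not None and cal.biopsy_time is not None:
        dt_s = (cal.readout_time - cal.biopsy_time).total_seconds()
        if dt_s < 0:
            raise ValueError("biopsy time must precede the readout reference")
    else:
        dt_s = 0.0
    factor = float(np.exp(chain.lambda_ra_per_s * dt_s))
    a_bx = a_ref * factor
    n_floored = int((a_bx < 0).sum())
    if background_mask is None:
        bg_vals = np.sort(a_bx.ravel())[: max(4, a_bx.size // 4)]
    else:
        bg_vals = a_bx[background_mask]
    lod = float(3.0 * bg_vals.std()) if bg_vals.size else float("nan")
    return ActivityMap(bq_per_voxel=np.maximum(a_bx, 0.0),
                       limit_of_detection_bq=lod, n_floored=n_floored)


def cumulated_activity(a_bq, chain: DecayChainData = RA223_CHAIN):
    """Cumulated activity A_tilde (Bq*s) by extrapolation to infinity.

    Integral of ``a * exp(-lambda_Ra t)`` from 0 to infinity = ``a / lambda``;
    physical decay only ("fixed in bone"), a maximally conservative estimate.
    Daughters are counted through Delta, not separate A_tilde terms.
    """
    a = np.asarray(a_bq, dtype=float)
    if (a < 0).any():
        raise ValueError("activity must be non-negative")
    out = a / chain.lambda_ra_per_s
    return float(out) if np.isscalar(a_bq) else out


def voxel_mass(compartment: str, consts: DosimetryConstants = DosimetryConstants()) -> float:
    """Mass (g) of one dosimetry voxel of the given compartment."""
    if compartment == "bone_core":
        rho = consts.rho_bone_g_cm3
    elif compartment in ("tissue_core", "interface"):
        rho = consts.rho_soft_g_cm3
    else:
        raise ValueError(f"no dose is reported for compartment {compartment!r}")
    return rho * consts.voxel_volume_cm3


def compute_dose_map(activity: ActivityMap, masks: CompartmentMaskSet,
                     consts: DosimetryConstants = DosimetryConstants(),
                     chain: DecayChainData = RA223_CHAIN) -> DoseMap:
    """MIRD voxel dose map: D = A_tilde * Delta * phi / mass, per voxel.

    Background voxels receive zero and are excluded from all statistics.
    """
    a = activity.bq_per_voxel
    if a.shape != masks.shape:
        raise ValueError("activity map and compartment masks must share a grid")
    delta = consts.delta_J_per_Bq_s if consts.delta_J_per_Bq_s is not None else delta_constant(chain)
    a_tilde = cumulated_activity(a, chain)
    dose = np.zeros_like(a, dtype=float)
    for comp in ("bone_core", "tissue_core", "interface"):
        m = getattr(masks, comp)
        if m.any():
            dose[m] = a_tilde[m] * delta * consts.phi / (voxel_mass(comp, consts) * 1e-3)  # g -> kg
    return DoseMap(gy_per_voxel=dose, maskset=masks)
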