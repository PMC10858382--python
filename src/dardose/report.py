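"""Figures of merit: compartment histograms, SD-tranche volumes, dose
statistics, bulk concentrations and correlation summaries.

Conventions used throughout (recorded in the output metadata): population
standard deviations; strict ``>`` for tranche membership; the tranche
mean/SD is computed section-wide over all non-background voxels by default
(a per-compartment basis is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import CompartmentMaskSet
from .quantify import DoseMap

__all__ = [
    "SampleSummary",
    "compartment_histogram",
    "tranche_volumes",
    "dose_stats",
    "sample_summary",
    "pearson_correlation",
]

_COMPARTMENTS = ("bone_core", "tissue_core", "interface")


@dataclass
class SampleSummary:
    """Bulk activity summary of one sample."""

    total_activity_bq: float
    sample_volume_mm3: float
    concentration_bq_mm3: float
    concentration_per_admin_bq_mm3_MBq: float
    administered_MBq: float


def compartment_histogram(value_map: np.ndarray, maskset: CompartmentMaskSet,
                          compartment: str, n_bins: int = 32,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of a per-voxel map within one compartment.

    Returns ``(counts, bin_edges)``; an empty compartment yields an empty
    histogram with a warning flag via zero-length counts.
    """
    mask = getattr(maskset, compartment)
    vals = np.asarray(value_map, dtype=float)[mask]
    if vals.size == 0:
        return np.array([], dtype=int), np.array([])
    if np.ptp(vals) == 0:
        # single occupied bin around the constant value
        edges = np.linspace(vals[0] - 0.5, vals[0] + 0.5, n_bins + 1)
        counts, edges = np.histogram(vals, bins=edges)
        return counts, edges
    counts, edges = np.histogram(vals, bins=n_bins)
    return counts, edges


def tranche_volumes(value_map: np.ndarray, maskset: CompartmentMaskSet,
                    voxel_volume_mm3: float,
                    per_compartment_basis: bool = False) -> pd.DataFrame:
    """Fraction and volume of each compartment above mean + 1 or 2 SD.

    The mean and population SD are taken over all non-background voxels of
    the section (or per compartment with ``per_compartment_basis=True``);
    membership is strictly above the threshold, so a constant section has
    empty tranches.
    """
    vals = np.asarray(value_map, dtype=float)
    section = ~maskset.background
    if not section.any():
        raise ValueError("section contains only background")
    rows = []
    if not per_compartment_basis:
        mu, sd = vals[section].mean(), vals[section].std()
    for comp in _COMPARTMENTS:
        mask = getattr(maskset, comp)
        n = int(mask.sum())
        if n == 0:
            continue
        if per_compartment_basis:
            mu, sd = vals[mask].mean(), vals[mask].std()
        f1 = float((vals[mask] > mu + sd).mean())
        f2 = float((vals[mask] > mu + 2 * sd).mean())
        rows.append({
            "compartment": comp, "n_voxels": n,
            "frac_above_mean_plus_1sd": f1, "frac_above_mean_plus_2sd": f2,
            "volume_above_1sd_mm3": f1 * n * voxel_volume_mm3,
            "volume_above_2sd_mm3": f2 * n * voxel_volume_mm3,
            "basis": "per_compartment" if per_compartment_basis else "section",
            "sd_convention": "population", "membership": "strict",
        })
    return pd.DataFrame(rows)


def dose_stats(dosemap: DoseMap, voxel_volume_mm3: float,
               activity_map: np.ndarray | None = None) -> pd.DataFrame:
    """Per-compartment and whole-section dose statistics.

    One row per non-empty compartment plus a ``whole_section`` row pooling
    the three tissue compartments; empty compartments are absent, not zero.
    """
    dose = dosemap.gy_per_voxel
    maskset = dosemap.maskset
    rows = []
    pooled = np.zeros(maskset.shape, dtype=bool)
    for comp in _COMPARTMENTS:
        mask = getattr(maskset, comp)
        pooled |= mask
        if not mask.any():
            continue
        rows.append(_stats_row(comp, dose, mask, voxel_volume_mm3, activity_map))
    if pooled.any():
        rows.append(_stats_row("whole_section", dose, pooled, voxel_volume_mm3, activity_map))
    return pd.DataFrame(rows)


def _stats_row(name, dose, mask, voxel_volume_mm3, activity_map):
    d = dose[mask]
    row = {
        "compartment": name,
        "n_voxels": int(mask.sum()),
        "mean_dose_gy": float(d.mean()),
        "max_dose_gy": float(d.max()),
        "sd_dose_gy": float(d.std()),
        "volume_mm3": float(mask.sum() * voxel_volume_mm3),
    }
    if activity_map is not None:
        row["mean_activity_bq"] = float(np.asarray(activity_map, float)[mask].mean())
    return row


def sample_summary(total_bq: float, volume_mm3: float,
                   administered_MBq: float) -> SampleSummary:
    """Bulk concentration and administered-activity normalization."""
    if volume_mm3 <= 0:
        raise ValueError("sample volume must be > 0")
    if administered_MBq <= 0:
        raise ValueError("administered activity must be > 0")
    conc = total_bq / volume_mm3
    return SampleSummary(
        total_activity_bq=float(total_bq),
        sample_volume_mm3=float(volume_mm3),
        concentration_bq_mm3=float(conc),
        concentration_per_admin_bq_mm3_MBq=float(conc / administered_MBq),
        administered_MBq=float(administered_MBq),
    )


def pearson_correlation(x, y, exclude_ids: tuple[int, ...] = ()) -> tuple[float, int]:
    """Pearson r after removing an explicit list of point indices.

    Outlier handling is caller-provided only — there is no automatic rule.
    Returns ``(r, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.ones(len(x), dtype=bool)
    keep[list(exclude_ids)] = False
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points after exclusion")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(len(x))
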