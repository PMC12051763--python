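"""Phantom-calibrated lesion detectability on ²¹²Pb γ-camera images.

Whether a structure is visible on SPECT depends on its activity
concentration and its volume: hot-sphere contrast,

    contrast = (mean counts in sphere − background) / background,

measured in a phantom across sphere sizes and concentrations defines a
monotone surface over (concentration, volume).  A structure is called
detectable when its predicted concentration exceeds the smallest
concentration whose contrast reaches a threshold C* at its volume.

Because real phantom tables are not always available, a simple
threshold rule is also provided: detectable iff concentration
≥ 4 kBq/mL and volume ≥ 1.5 cm³ (box volume; 1 cm³ when dimensions are
absent).  The map-based path is primary; the rule is a documented
fallback calibrated to the same qualitative behaviour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.isotonic import IsotonicRegression

from .uptake import UptakeEstimate

FALLBACK_CONC_THRESHOLD_KBQ_ML = 4.0
FALLBACK_VOLUME_THRESHOLD_CM3 = 1.5
DEFAULT_CONTRAST_THRESHOLD = 0.30


@dataclass(frozen=True)
class ContrastObservation:
    """One phantom measurement: sphere volume, concentration, contrast."""

    sphere_volume_cm3: float
    concentration_kBq_mL: float
    contrast: float

    def __post_init__(self) -> None:
        if self.sphere_volume_cm3 <= 0:
            raise ValueError("sphere volume must be positive")
        if self.concentration_kBq_mL < 0:
            raise ValueError("concentration must be non-negative")


class CalibrationError(ValueError):
    """Observations do not span both axes of the contrast surface."""


@dataclass
class ContrastMap:
    """Isotonic contrast surface over (concentration, volume).

    ``contrast`` is an (n_conc, n_vol) grid, non-decreasing along both
    axes; queries are bilinear between nodes and clamped to the nearest
    node outside the calibrated range.
    """

    conc_grid: np.ndarray
    vol_grid: np.ndarray
    contrast: np.ndarray
    threshold: float = DEFAULT_CONTRAST_THRESHOLD

    def __post_init__(self) -> None:
        self.conc_grid = np.asarray(self.conc_grid, dtype=float)
        self.vol_grid = np.asarray(self.vol_grid, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (len(self.conc_grid), len(self.vol_grid)):
            raise ValueError("contrast grid shape mismatch")
        if np.any(np.diff(self.contrast, axis=0) < -1e-9) or np.any(
            np.diff(self.contrast, axis=1) < -1e-9
        ):
            raise ValueError("contrast surface must be non-decreasing on both axes")
        self._interp = RegularGridInterpolator(
            (self.conc_grid, self.vol_grid),
            self.contrast,
            method="linear",
            bounds_error=False,
            fill_value=None,  # linear extrapolation, clamped below
        )

    def __call__(self, concentration: float, volume: float) -> float:
        """Contrast at (concentration, volume), clamped to the grid range."""
        c = float(np.clip(concentration, self.conc_grid[0], self.conc_grid[-1]))
        v = float(np.clip(volume, self.vol_grid[0], self.vol_grid[-1]))
        if concentration == 0:
            return 0.0
        return float(self._interp((c, v)))


def _isotonic_2d(grid: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Cyclic row/column isotonic projection onto bimonotone surfaces."""
    z = grid.copy()
    iso = IsotonicRegression(increasing=True)
    for _ in range(max_iter):
        prev = z.copy()
        for i in range(z.shape[0]):
            z[i, :] = iso.fit_transform(np.arange(z.shape[1]), z[i, :])
        for j in range(z.shape[1]):
            z[:, j] = iso.fit_transform(np.arange(z.shape[0]), z[:, j])
        if np.max(np.abs(z - prev)) < tol:
            break
    return z


def calibrate_contrast_map(
    observations: list[ContrastObservation],
    threshold: float = DEFAULT_CONTRAST_THRESHOLD,
) -> ContrastMap:
    """Fit the monotone contrast surface from phantom observations.

    Observations are averaged per (concentration, volume) node, gaps are
    filled by per-axis linear interpolation, and the grid is projected
    onto the bimonotone cone by cyclic isotonic regression.  Requires at
    least 4 observations spanning ≥ 2 distinct values on each axis.
    """
    if len(observations) < 4:
        raise CalibrationError("need at least 4 phantom observations")
    df = pd.DataFrame(
        {
            "conc": [o.concentration_kBq_mL for o in observations],
            "vol": [o.sphere_volume_cm3 for o in observations],
            "contrast": [o.contrast for o in observations],
        }
    )
    if df["conc"].nunique() < 2 or df["vol"].nunique() < 2:
        raise CalibrationError("observations must span both axes")
    pivot = df.pivot_table(index="conc", columns="vol", values="contrast", aggfunc="mean")
    grid = pivot.to_numpy()
    # fill sparse nodes along concentration, then volume
    filled = (
        pd.DataFrame(grid, index=pivot.index, columns=pivot.columns)
        .interpolate(axis=0, limit_direction="both")
        .interpolate(axis=1, limit_direction="both")
        .to_numpy()
    )
    if np.isnan(filled).any():
        raise CalibrationError("contrast grid could not be filled from observations")
    mono = _isotonic_2d(filled)
    return ContrastMap(
        conc_grid=pivot.index.to_numpy(float),
        vol_grid=pivot.columns.to_numpy(float),
        contrast=mono,
        threshold=threshold,
    )


def min_detectable_concentration(cmap: ContrastMap, volume: float) -> float:
    """Smallest concentration whose contrast reaches the threshold at ``volume``.

    Clamped to the calibrated concentration range: never reports below
    the phantom floor (the lowest measured concentration), and returns
    ``inf`` when no calibrated concentration reaches the threshold.
    Non-increasing in volume.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if volume < cmap.vol_grid[0] or volume > cmap.vol_grid[-1]:
        warnings.warn(
            f"volume {volume:.3g} cm3 outside calibrated range "
            f"[{cmap.vol_grid[0]:.3g}, {cmap.vol_grid[-1]:.3g}]; clamped",
            stacklevel=2,
        )
    lo, hi = cmap.conc_grid[0], cmap.conc_grid[-1]
    if cmap(hi, volume) < cmap.threshold:
        return math.inf
    if cmap(lo, volume) >= cmap.threshold:
        return float(lo)
    for _ in range(80):  # bisection on a monotone section
        mid = 0.5 * (lo + hi)
        if cmap(mid, volume) >= cmap.threshold:
            hi = mid
        else:
            lo = mid
    return float(hi)


def classify_detectable(
    estimate: UptakeEstimate, cmap: ContrastMap | None = None
) -> bool:
    """Detectability call for one uptake estimate.

    With a calibrated map: detectable iff the concentration reaches the
    minimum detectable concentration at the structure's volume.  Without
    a map, the fallback threshold rule is applied.
    """
    if cmap is None:
        return fallback_detectable(estimate.concentration_kBq_mL, estimate.volume_cm3)
    if estimate.concentration_kBq_mL == 0:
        return False
    return estimate.concentration_kBq_mL >= min_detectable_concentration(
        cmap, estimate.volume_cm3
    )


def fallback_detectable(concentration_kBq_mL: float, volume_cm3: float) -> bool:
    """Threshold rule: concentration ≥ 4 kBq/mL and volume ≥ 1.5 cm³."""
    return (
        concentration_kBq_mL >= FALLBACK_CONC_THRESHOLD_KBQ_ML
        and volume_cm3 >= FALLBACK_VOLUME_THRESHOLD_CM3
    )


def read_phantom_csv(path) -> list[ContrastObservation]:
    """Read a phantom CSV (volume_cm3,conc_kBq_mL,contrast)."""
    df = pd.read_csv(path)
    required = {"volume_cm3", "conc_kBq_mL", "contrast"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phantom CSV missing columns: {sorted(missing)}")
    return [
        ContrastObservation(float(r.volume_cm3), float(r.conc_kBq_mL), float(r.contrast))
        for r in df.itertuples(index=False)
    ]
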