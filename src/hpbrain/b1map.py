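"""Transmit (B1) calibration by sine fitting of a variable-flip-angle series.

A thermal phantom (or any steady signal source) imaged at a ladder of nominal
flip angles ``theta`` produces magnitudes ``S(theta) = S0 sin(kappa theta)``,
where ``kappa`` is the ratio of achieved to nominal flip angle.  Fitting the
two-parameter sine per voxel yields a B1 scale map; ``kappa = 0.84`` means the
coil delivers 84% of the prescribed flip angle at that location.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class FlipSeries:
    """Signal magnitudes acquired at a ladder of nominal flip angles.

    ``angles_deg`` must be strictly increasing with at least three entries;
    ``signals`` are non-negative magnitudes of matching length (1-D for a
    single location, or ``(n_angles, ...)`` for maps).
    """

    angles_deg: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "angles_deg",
                           np.asarray(self.angles_deg, dtype=float))
        object.__setattr__(self, "signals",
                           np.asarray(self.signals, dtype=float))
        a = self.angles_deg
        if a.ndim != 1 or len(a) < 3:
            raise ValueError("need at least 3 flip angles")
        if not np.all(np.diff(a) > 0):
            raise ValueError("flip angles must be strictly increasing")
        if self.signals.shape[0] != len(a):
            raise ValueError("signals first axis must match the angle count")
        if np.any(self.signals < 0) or not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite and non-negative")


@dataclass(frozen=True)
class FlipScaleFit:
    """Fitted B1 scale for one location (NaN when there is no signal)."""

    kappa: float
    s0: float
    residual_norm: float

    @property
    def kappa_percent(self) -> float:
        """Achieved flip angle as a percentage of nominal."""
        return 100.0 * self.kappa


def _fit_one(theta_rad: np.ndarray, s: np.ndarray) -> FlipScaleFit:
    if not np.any(s > 0):
        return FlipScaleFit(kappa=np.nan, s0=np.nan, residual_norm=np.nan)
    s0_guess = s.max()
    best = None
    # magnitude images cannot go negative, so the model is |S0 sin(kappa
    # theta)|; for kappa > 1 the sine crosses zero inside a 70-180 deg ladder
    for kappa0 in (0.7, 1.0, 1.3):
        res = least_squares(
            lambda x: np.abs(x[0] * np.sin(x[1] * theta_rad)) - s,
            x0=[s0_guess, kappa0], method="trf",
            bounds=([0.0, 1e-6], [np.inf, 2.0]))
        if best is None or res.cost < best.cost:
            best = res
    denom = np.linalg.norm(s)
    return FlipScaleFit(kappa=float(best.x[1]), s0=float(best.x[0]),
                        residual_norm=float(np.sqrt(2 * best.cost) / denom))


def fit_flip_scale(series: FlipSeries) -> FlipScaleFit:
    """Fit ``S0 sin(kappa theta)`` to one location's flip-angle series.

    Bounded nonlinear least squares from several ``kappa`` starting points,
    constrained to ``kappa`` in (0, 2].  An all-zero series yields NaNs.
    """
    if series.signals.ndim != 1:
        raise ValueError("fit_flip_scale expects a single location; "
                         "use fit_flip_scale_map for maps")
    return _fit_one(np.deg2rad(series.angles_deg), series.signals)


def fit_flip_scale_map(series: FlipSeries,
                       mask: Optional[np.ndarray] = None) -> dict:
    """Per-voxel B1 scale maps from a flip-angle image series.

    ``series.signals`` is ``(n_angles, ...)``; returns ``kappa``, ``s0`` and
    ``residual_norm`` maps (NaN outside the mask and at zero-signal voxels).
    """
    sig = series.signals
    if sig.ndim < 2:
        raise ValueError("map fitting needs signals with spatial axes")
    theta = np.deg2rad(series.angles_deg)
    spatial = sig.shape[1:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape does not match the signal spatial axes")
    kappa = np.full(spatial, np.nan)
    s0 = np.full(spatial, np.nan)
    resid = np.full(spatial, np.nan)
    flat = sig.reshape(len(theta), -1)
    kf, sf, rf = kappa.ravel(), s0.ravel(), resid.ravel()
    for i in np.nonzero(mask.ravel())[0]:
        fit = _fit_one(theta, flat[:, i])
        kf[i], sf[i], rf[i] = fit.kappa, fit.s0, fit.residual_norm
    return {"kappa": kappa, "s0": s0, "residual_norm": resid}
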