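"""Estimation of (D_inf, c_D) from a D(t) curve.

D(t) is linear in 1/sqrt(t) in the long-time regime, so the fit is an
ordinary least-squares regression of D against 1/sqrt(t).  The central
estimate uses the [10, 500] ms window; the uncertainty is the spread of the
fitted parameters over a sweep of plausible lower cutoffs t0 in [3, 10] ms —
a model-range uncertainty rather than a within-fit statistical error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .theory import DtCurve

__all__ = ["DtFit", "fit_dt", "propagate_dt_uncertainty"]

DEFAULT_T0_GRID = tuple(float(t) for t in range(3, 11))   # 3..10 ms, 1 ms steps


@dataclass
class DtFit:
    Dinf: float
    cD: float
    Dinf_sd: float
    cD_sd: float
    fit_range: tuple
    t0_grid: tuple
    flagged: bool = False       # nonpositive fitted Dinf (wrong regime)

    def __post_init__(self) -> None:
        if self.Dinf_sd < 0 or self.cD_sd < 0:
            raise ValueError("sds must be nonnegative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"Dinf": self.Dinf, "cD": self.cD, "Dinf_sd": self.Dinf_sd,
                 "cD_sd": self.cD_sd, "fit_range_ms": list(self.fit_range),
                 "t0_grid_ms": list(self.t0_grid), "flagged": self.flagged},
                fh, indent=2,
            )


def _ols(t, d, weights=None):
    """Least squares of d against 1/sqrt(t); returns (intercept Dinf, slope cD)."""
    x = 1.0 / np.sqrt(t)
    w = np.ones_like(x) if weights is None else weights
    coeffs = np.polyfit(x, d, 1, w=np.sqrt(w))
    return float(coeffs[1]), float(coeffs[0])


def fit_dt(
    curve: DtCurve,
    t_min: float = 10.0,
    t_max: float = 500.0,
    t0_grid=DEFAULT_T0_GRID,
    weighted: bool = False,
) -> DtFit:
    """Fit D(t) = D_inf + c_D/sqrt(t) with the t0-sweep uncertainty.

    Central estimates come from the [t_min, t_max] window; the reported sds
    are the standard deviations of (D_inf, c_D) over refits with the lower
    bound replaced by each t0 in ``t0_grid``.  With ``weighted=True`` and
    per-point sd on the curve, inverse-variance weights are applied.
    """
    t0_grid = tuple(float(t) for t in t0_grid)
    if t_max <= max(t0_grid):
        raise ValueError("t_max must exceed max(t0_grid)")
    t, d = curve.t, curve.D
    weights = None
    if weighted and curve.sd is not None:
        sd = np.where(curve.sd > 0, curve.sd, np.inf)
        weights = 1.0 / sd**2

    def window(lo):
        mask = (t >= lo) & (t <= t_max)
        if mask.sum() < 6:
            raise ValueError(
                f"fewer than 6 points in the fit window [{lo}, {t_max}] ms"
            )
        w = weights[mask] if weights is not None else None
        return _ols(t[mask], d[mask], w)

    dinf, cd = window(t_min)
    sweep = np.array([window(t0) for t0 in t0_grid])
    return DtFit(
        Dinf=dinf,
        cD=cd,
        Dinf_sd=float(sweep[:, 0].std(ddof=0)),
        cD_sd=float(sweep[:, 1].std(ddof=0)),
        fit_range=(t_min, t_max),
        t0_grid=t0_grid,
        flagged=dinf <= 0,
    )


def propagate_dt_uncertainty(fit: DtFit, t) -> np.ndarray:
    """sigma_D(t) = sqrt(sigma_Dinf^2 + sigma_cD^2 / t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    return np.sqrt(fit.Dinf_sd**2 + fit.cD_sd**2 / t)
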