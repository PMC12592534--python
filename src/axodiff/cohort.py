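"""Population-level statistics for two-group axon cohorts.

Three pieces: volume-weighted ensemble curves (the dMRI-accessible D(t) is
the weighted mean of per-axon curves), a nonparametric effect size

    d_eff = (median(X) - median(Y)) / PMAD_XY,

where each group's MAD is taken about its Hodges-Lehmann pseudo-median
(median of all Walsh averages) and pooled with (n-1) degrees-of-freedom
weights, and a maximum-margin linear projection: the SVM normal in a 2-D
parameter plane (tortuosity vs Gamma_0, or D_inf vs c_D) defines the single
score z that best separates injured from control populations.  No hypothesis
tests are computed, by design: with thousands of axons per group, effect
sizes are the meaningful summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .theory import DtCurve

__all__ = [
    "EffectSize",
    "MaxMarginResult",
    "ensemble_curve",
    "hodges_lehmann",
    "mad",
    "effect_size",
    "max_margin_projection",
    "read_cohort_table",
    "write_cohort_table",
]

COHORT_COLUMNS = ["axon_id", "group", "tortuosity", "gamma0_um", "Dinf", "cD", "weight", "xi"]


@dataclass
class EffectSize:
    d_eff: float
    median_x: float
    median_y: float
    pooled_mad: float


@dataclass
class MaxMarginResult:
    z_x: np.ndarray
    z_y: np.ndarray
    normal: np.ndarray           # unit normal in original coordinates
    offset: float
    d_eff: float
    seed: int


def ensemble_curve(curves: list[DtCurve], weights, interpolate: bool = False) -> DtCurve:
    """Volume-weighted ensemble D(t) = sum_i w_i D_i(t), with weighted sd.

    Curves must share a common time grid unless ``interpolate=True``, in which
    case all curves are linearly interpolated onto the first curve's grid
    (restricted to the overlap of all time ranges).
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    w = np.asarray(weights, dtype=float)
    if w.size != len(curves) or np.any(w < 0):
        raise ValueError("weights must be nonnegative, one per curve")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")

    base = curves[0].t
    if interpolate:
        lo = max(c.t[0] for c in curves)
        hi = min(c.t[-1] for c in curves)
        base = base[(base >= lo) & (base <= hi)]
        values = np.vstack([np.interp(base, c.t, c.D) for c in curves])
    else:
        for c in curves:
            if c.t.shape != base.shape or not np.allclose(c.t, base, rtol=1e-9):
                raise ValueError("curves are on mismatched time grids; pass interpolate=True")
        values = np.vstack([c.D for c in curves])

    mean = w @ values
    sd = np.sqrt(np.maximum(w @ (values - mean) ** 2, 0.0))
    return DtCurve(t=base, D=mean, sd=sd, kind=curves[0].kind)


def hodges_lehmann(x: np.ndarray) -> float:
    """Hodges-Lehmann pseudo-median: median of all Walsh averages (i <= j)."""
    x = np.asarray(x, dtype=float)
    i, j = np.triu_indices(x.size)
    return float(np.median((x[i] + x[j]) / 2.0))


def mad(x: np.ndarray, center: str = "hl") -> float:
    """Median absolute deviation about the HL pseudo-median (or plain median)."""
    x = np.asarray(x, dtype=float)
    c = hodges_lehmann(x) if center == "hl" else float(np.median(x))
    return float(np.median(np.abs(x - c)))


def effect_size(sample_x, sample_y, center: str = "hl") -> EffectSize:
    """Nonparametric effect size d_eff = (median X - median Y) / pooled MAD."""
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs >= 5 values")
    mad_x, mad_y = mad(x, center), mad(y, center)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * mad_x**2 + (ny - 1) * mad_y**2) / (nx + ny - 2))
    if pooled == 0.0:
        raise ValueError("pooled MAD is zero (both samples constant): d_eff undefined")
    return EffectSize(
        d_eff=float((np.median(x) - np.median(y)) / pooled),
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
        pooled_mad=float(pooled),
    )


def max_margin_projection(
    points_x: np.ndarray,
    points_y: np.ndarray,
    seed: int = 0,
    C: float = 1.0,
) -> MaxMarginResult:
    """Maximum-margin separation of two groups in a 2-D parameter plane.

    The larger group is subsampled without replacement to the smaller group's
    size (seeded), features are robustly standardized (median/MAD over the
    balanced training set), and a soft-margin linear SVM is fitted.  Every
    original point's signed distance to the hyperplane is returned as its
    z-score, oriented so that group X (control) has the lower median; d_eff
    between the two z distributions summarizes the separation.
    """
    X = np.atleast_2d(np.asarray(points_x, dtype=float))
    Y = np.atleast_2d(np.asarray(points_y, dtype=float))
    if X.shape[0] < 10 or Y.shape[0] < 10:
        raise ValueError("each group needs >= 10 points")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("groups must share the feature dimension")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("coordinates must be finite")

    rng = np.random.default_rng(seed)
    n = min(X.shape[0], Y.shape[0])
    Xs = X[rng.choice(X.shape[0], n, replace=False)] if X.shape[0] > n else X
    Ys = Y[rng.choice(Y.shape[0], n, replace=False)] if Y.shape[0] > n else Y

    train = np.vstack([Xs, Ys])
    center = np.median(train, axis=0)
    scale = np.median(np.abs(train - center), axis=0)
    if np.any(scale == 0):
        raise ValueError("degenerate points: zero MAD in some feature")
    labels = np.concatenate([np.zeros(n), np.ones(n)])

    svm = LinearSVC(C=C, loss="squared_hinge", max_iter=100000, random_state=0)
    svm.fit((train - center) / scale, labels)
    w_std = svm.coef_[0]
    b_std = float(svm.intercept_[0])
    if np.allclose(w_std, 0):
        raise ValueError("SVM produced a degenerate (zero) normal")

    # back to original coordinates: w.(p - center)/scale + b
    w_orig = w_std / scale
    norm = np.linalg.norm(w_orig)
    w_unit = w_orig / norm
    offset = (b_std - np.dot(w_std, center / scale)) / norm

    z_x = X @ w_unit + offset
    z_y = Y @ w_unit + offset
    if np.median(z_x) > np.median(z_y):
        w_unit, offset, z_x, z_y = -w_unit, -offset, -z_x, -z_y
    d = effect_size(z_y, z_x).d_eff     # positive when group Y shifts up
    return MaxMarginResult(z_x=z_x, z_y=z_y, normal=w_unit, offset=float(offset),
                           d_eff=float(d), seed=seed)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g", columns=COHORT_COLUMNS)
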