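"""Power spectral density of the log-area field and its low-q plateau.

The PSD follows the continuum convention Gamma_eta(q) = |eta_q|^2 / L with
eta_q = sum_j eta_j exp(-i q l_j) dl and L = N dl, so Gamma carries units of
length (um).  The q -> 0 plateau Gamma_0 is the single number that, together
with D_inf, fixes the amplitude c_D = 2 Gamma_0 sqrt(D_inf/pi) of the 1/sqrt(t)
tail of D(t) for short-range disorder.

The plateau estimate sweeps a grid of variance fractions beta: for each beta a
low-q cutoff is placed so that wavevectors above it carry fraction beta of the
total spectral variance, and Gamma_0(beta) is the mean of Gamma_eta over the
remaining lowest bins (at least 3).  The mean and standard deviation over the
beta grid give the estimate and its uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectralDensity", "PlateauEstimate", "psd", "plateau",
           "spectral_variance", "write_spectrum", "write_plateau"]

DEFAULT_BETA_GRID = (0.92, 0.93, 0.94, 0.95, 0.96, 0.97)


@dataclass
class SpectralDensity:
    """One-sided PSD of eta on the positive DFT wavevector grid (q = 0 excluded).

    ``fold_weights`` counts how many of the +-q bins each stored bin represents
    (2 for interior bins of a real signal, 1 for the Nyquist bin), so that
    Parseval sums can be taken over the one-sided grid.
    """

    q: np.ndarray            # rad/um, ascending, positive
    gamma: np.ndarray        # um
    record_length: float     # um
    dl: float                # um
    fold_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.gamma < 0):
            raise ValueError("Gamma_eta(q) must be nonnegative")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0):
            raise ValueError("q grid must be positive ascending")
        if self.fold_weights is None:
            self.fold_weights = np.full(self.q.size, 2.0)
        else:
            self.fold_weights = np.asarray(self.fold_weights, dtype=float)

    @property
    def dq(self) -> float:
        """Wavevector spacing 2 pi / L in rad/um."""
        return 2.0 * np.pi / self.record_length


@dataclass
class PlateauEstimate:
    gamma0: float
    gamma0_sd: float
    beta_grid: tuple
    min_bins_forced: bool = False

    def __post_init__(self) -> None:
        if self.gamma0 < 0 or self.gamma0_sd < 0:
            raise ValueError("gamma0 and gamma0_sd must be nonnegative")


def psd(eta: np.ndarray, dl: float, segment_length: int | None = None) -> SpectralDensity:
    """Periodogram of eta with the continuum normalization Gamma = |eta_q|^2/L.

    The mean of eta is subtracted before the transform (only fluctuations
    matter at q != 0; centering suppresses leakage from the DC bin).  No taper
    is applied.  With ``segment_length`` set, non-overlapping segments are
    averaged (Welch without a window), trading resolution for variance.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 1:
        raise ValueError("eta must be 1-D")
    if eta.size < 16:
        raise ValueError(f"need >= 16 samples, got {eta.size}")
    if dl <= 0:
        raise ValueError("dl must be positive")

    if segment_length is None:
        segments = [eta]
    else:
        if segment_length < 16 or segment_length > eta.size:
            raise ValueError("segment_length must be in [16, len(eta)]")
        n_seg = eta.size // segment_length
        segments = [eta[i * segment_length:(i + 1) * segment_length] for i in range(n_seg)]

    n = segments[0].size
    length = n * dl
    spec = np.zeros(n // 2)
    for seg in segments:
        coeff = np.fft.rfft(seg - seg.mean()) * dl
        spec += np.abs(coeff[1:]) ** 2 / length
    spec /= len(segments)
    q = 2.0 * np.pi * np.arange(1, n // 2 + 1) / length
    fold = np.full(n // 2, 2.0)
    if n % 2 == 0:
        fold[-1] = 1.0  # Nyquist bin has no mirror
    return SpectralDensity(q=q, gamma=spec, record_length=length, dl=dl,
                           fold_weights=fold, n_segments=len(segments))


def spectral_variance(spec: SpectralDensity) -> float:
    """(1/2pi) sum over +-q of Gamma(q) dq; equals var(eta) for a plain periodogram."""
    return float(np.sum(spec.fold_weights * spec.gamma) * spec.dq / (2.0 * np.pi))


def plateau(spec: SpectralDensity, beta_grid=DEFAULT_BETA_GRID) -> PlateauEstimate:
    """Estimate the q -> 0 plateau Gamma_0 with a variance-fraction sweep.

    For each fraction beta the cutoff q_beta is the largest wavevector such
    that bins above it carry at least fraction beta of the total spectral
    variance; Gamma_0(beta) averages Gamma over the bins at or below q_beta,
    with a floor of 3 bins.
    """
    beta_grid = tuple(beta_grid)
    if any(not (0.5 < b < 1.0) for b in beta_grid):
        raise ValueError("beta fractions must lie in (0.5, 1)")
    if spec.q.size < 8:
        raise ValueError("spectrum must have >= 8 bins")

    contrib = spec.fold_weights * spec.gamma       # per-bin variance weight
    total = contrib.sum()
    forced = False
    values = []
    if total == 0.0:
        return PlateauEstimate(0.0, 0.0, beta_grid)
    cum = np.cumsum(contrib)
    for beta in beta_grid:
        # keep the largest low-q block whose variance share is <= (1 - beta)
        n_low = int(np.searchsorted(cum, (1.0 - beta) * total, side="right"))
        if n_low < 3:
            n_low = 3
            forced = True
        values.append(float(spec.gamma[:n_low].mean()))
    values = np.asarray(values)
    return PlateauEstimate(
        gamma0=float(values.mean()),
        gamma0_sd=float(values.std(ddof=0)),
        beta_grid=beta_grid,
        min_bins_forced=forced,
    )


def write_spectrum(spec: SpectralDensity, path) -> None:
    pd.DataFrame({"q_rad_per_um": spec.q, "gamma_eta_um": spec.gamma}).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def write_plateau(est: PlateauEstimate, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"gamma0_um": est.gamma0, "gamma0_sd_um": est.gamma0_sd,
             "beta_grid": list(est.beta_grid), "min_bins_forced": est.min_bins_forced},
            fh, indent=2,
        )
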