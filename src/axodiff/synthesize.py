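"""Synthetic axon profiles with controlled structural disorder.

Two generators:

* ``generate_bead_profile`` — the randomly-placed-bead model: cross-sectional
  area A(x) = A0 + n(x) * A1 G_sigma1(x), where n(x) is a renewal point
  process of bead centers with normally distributed inter-bead intervals
  (mean abar, SD sigma_a, truncated below at 2 dl) and G is a unit-mass
  Gaussian kernel of width sigma1.  This is short-range disorder with a
  finite PSD plateau; for small beads the plateau approaches the single-bead
  prediction Gamma_0 = (sigma_a^2/abar) phi^2 with phi = A1/(Abar abar).

* ``generate_spectrum_profile`` — a Gaussian random field eta with a
  prescribed low-q spectrum C |q|^p rolled off beyond 1/lc, exponentiated to
  A = Abar e^eta; used to probe the universality classes of the D(t) tail.

Defaults: A0 = pi (0.5)^2 um^2 with per-bead parameters inside the ranges
A1 in [0.1, 2.5] um^2, sigma1 in [3, 7] um, abar in [3, 7] um, sigma_a in
[0.8, 1.2] abar.  The single-profile defaults sit at the pronounced-beading
end of these ranges (largest amplitude, narrowest bead, strongest spacing
disorder, mid spacing): mid-range values, once smoothed by the wide kernel,
leave a nearly uniform tube whose diffusion time dependence is far weaker
than that of visibly beaded (injured-like) axons.  Cohort generation draws
per-axon parameters across the full ranges.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .geometry import AxonProfile

__all__ = ["BeadModelParams", "generate_bead_profile", "generate_spectrum_profile"]


@dataclass
class BeadModelParams:
    """Parameters of the randomly-placed-bead area generator (units um, um^2)."""

    base_area: float = math.pi * 0.25        # A0
    bead_amplitude: float = 2.5              # A1, range [0.1, 2.5]
    bead_width: float = 3.0                  # sigma1, range [3, 7]
    mean_spacing: float = 5.0                # abar, range [3, 7]
    sd_spacing: float = 6.0                  # sigma_a, range [0.8, 1.2]*abar
    length: float = 500.0                    # L
    dl: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_area <= 0:
            raise ValueError("base_area A0 must be positive")
        if self.bead_amplitude < 0:
            raise ValueError("bead_amplitude A1 must be nonnegative")
        if self.bead_width <= 0:
            raise ValueError("bead_width sigma1 must be positive")
        if self.mean_spacing <= 0:
            raise ValueError("mean_spacing abar must be positive")
        if self.sd_spacing < 0:
            raise ValueError("sd_spacing must be nonnegative")
        if self.length < 10 * self.mean_spacing:
            raise ValueError("length must be >= 10 * mean_spacing")
        if self.dl <= 0:
            raise ValueError("dl must be positive")

    def manifest(self) -> dict:
        return asdict(self)


def _draw_gaps(rng: np.random.Generator, n: int, abar: float, sd: float, lo: float):
    """Draw n inter-bead gaps from Normal(abar, sd) truncated below at lo."""
    gaps = np.empty(n)
    filled = 0
    rejected = 0
    while filled < n:
        draw = rng.normal(abar, sd, size=2 * (n - filled))
        ok = draw[draw >= lo]
        rejected += draw.size - ok.size
        take = min(ok.size, n - filled)
        gaps[filled:filled + take] = ok[:take]
        filled += take
    total = rejected + n
    return gaps, rejected / total


def generate_bead_profile(
    params: BeadModelParams,
    return_details: bool = False,
):
    """Generate a beaded-axon area profile on the uniform dl grid.

    Bead centers are placed sequentially with truncated-normal gaps on an
    extended domain (5 sigma1 + 5 abar margin on each side, so edge beads
    contribute at full kernel mass and the bead density carries no edge
    dilution), the unit-mass Gaussian kernel is summed directly at each
    center, and the profile is cropped to [0, L].  Deterministic given the
    seed.

    With ``return_details=True`` also returns a dict with the bead centers
    inside the window, the achieved gap moments (post-truncation), the
    truncation rejection fraction, and the generation manifest.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    pad = 5.0 * p.bead_width + 5.0 * p.mean_spacing
    lo, hi = -pad, p.length + pad

    # upper bound on bead count; gaps >= 2 dl guarantee termination
    n_guess = max(int((hi - lo) / max(p.mean_spacing, 2 * p.dl) * 1.5) + 20, 20)
    gaps = np.empty(0)
    rej_frac = 0.0
    while True:
        more, rf = _draw_gaps(rng, n_guess, p.mean_spacing, p.sd_spacing, 2 * p.dl)
        rej_frac = (rej_frac * gaps.size + rf * more.size) / (gaps.size + more.size)
        gaps = np.concatenate([gaps, more])
        if gaps.sum() > (hi - lo):
            break
    if rej_frac > 0.5:
        warnings.warn(
            f"gap truncation rejected {rej_frac:.0%} of draws (sd_spacing too "
            "large vs mean_spacing); proceeding with the truncated distribution",
            stacklevel=2,
        )
    start = lo + rng.uniform(0.0, p.mean_spacing)
    centers = start + np.cumsum(gaps)
    centers = centers[centers <= hi]

    n = int(np.floor(p.length / p.dl)) + 1
    grid = np.arange(n) * p.dl
    area = np.full(n, p.base_area)
    if p.bead_amplitude > 0:
        norm = p.bead_amplitude / math.sqrt(2.0 * math.pi * p.bead_width**2)
        half = 6.0 * p.bead_width
        inv2s2 = 1.0 / (2.0 * p.bead_width**2)
        for xm in centers:
            j0 = max(0, int(math.ceil((xm - half) / p.dl)))
            j1 = min(n - 1, int(math.floor((xm + half) / p.dl)))
            if j1 < j0:
                continue
            x = grid[j0:j1 + 1] - xm
            area[j0:j1 + 1] += norm * np.exp(-x * x * inv2s2)

    profile = AxonProfile(grid, area, axon_id=f"bead-seed{p.seed}")
    if not return_details:
        return profile
    inside = centers[(centers >= 0) & (centers <= p.length)]
    used = gaps[:centers.size]
    details = {
        "bead_centers": inside,
        "n_beads": int(inside.size),
        "achieved_gap_mean": float(used.mean()),
        "achieved_gap_sd": float(used.std(ddof=1)),
        "rejection_fraction": float(rej_frac),
        "manifest": p.manifest(),
    }
    return profile, details


def generate_spectrum_profile(
    p: float,
    C: float,
    corr_length: float = 1.0,
    var_target: float | None = None,
    L: float = 1000.0,
    dl: float = 0.1,
    seed: int = 0,
    mean_area: float = math.pi * 0.25,
    return_details: bool = False,
):
    """Gaussian random field eta with target spectrum C |q|^p e^{-(q lc)^2}.

    eta is synthesized by Fourier filtering of white noise so that
    E|eta_q|^2 = S(q) L; the area profile is A = Abar e^eta, positive by
    construction.  If ``var_target`` is given, the spectrum is rescaled so
    that the analytic variance (1/2pi) int S dq equals it (the realized
    amplitude is then reported in the details).
    """
    if p <= -1:
        raise ValueError("p must exceed -1 for an integrable spectrum")
    if C < 0:
        raise ValueError("amplitude C must be nonnegative")
    if corr_length <= 0 or L <= 0 or dl <= 0:
        raise ValueError("corr_length, L and dl must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.floor(L / dl)) + 1
    grid = np.arange(n) * dl
    length = n * dl
    q = 2.0 * np.pi * np.fft.rfftfreq(n, d=dl)

    spectrum = np.zeros_like(q)
    qpos = q[1:]
    spectrum[1:] = C * qpos**p * np.exp(-((qpos * corr_length) ** 2))
    scale = 1.0
    if var_target is not None:
        # analytic variance of the target spectrum over the +-q grid
        dq = 2.0 * np.pi / length
        fold = np.full(q.size, 2.0)
        fold[0] = 1.0
        if n % 2 == 0:
            fold[-1] = 1.0
        var_analytic = np.sum(fold * spectrum) * dq / (2.0 * np.pi)
        if var_analytic <= 0:
            raise ValueError("target spectrum has zero variance")
        scale = var_target / var_analytic
        spectrum = spectrum * scale

    amp = np.sqrt(spectrum * length) / dl       # E|FFT_k|^2 = S L / dl^2
    coeff = np.zeros(q.size, dtype=complex)
    interior = slice(1, q.size - 1 if n % 2 == 0 else q.size)
    m = coeff[interior].size
    coeff[interior] = amp[interior] * (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / math.sqrt(2.0)
    if n % 2 == 0:
        coeff[-1] = amp[-1] * rng.standard_normal()
    eta = np.fft.irfft(coeff, n=n)
    if np.exp(eta.min()) <= 0.05:
        warnings.warn("min alpha below 0.05: variance likely too large", stacklevel=2)
    area = mean_area * np.exp(eta)
    profile = AxonProfile(grid, area, axon_id=f"spectrum-p{p}-seed{seed}")
    if not return_details:
        return profile
    return profile, {
        "realized_amplitude": C * scale,
        "target_exponent": p,
        "corr_length": corr_length,
        "var_eta": float(eta.var()),
        "seed": seed,
    }
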