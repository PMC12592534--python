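"""Closed-form maps between axon geometry and time-dependent axial diffusion.

Forward direction: a relative profile alpha(l) and its PSD plateau Gamma_0
give the long-time diffusivity D_inf = D0 / (<1/alpha> xi^2) and the tail
amplitude c_D = 2 Gamma_0 sqrt(D_inf,l / pi) / xi^2, so that the cumulative
along-axon diffusion coefficient obeys

    D(t) ~= D_inf + c_D / sqrt(t),        t >> t_c,

with the dispersive (frequency-domain) counterpart
D(omega) ~= D_inf + (sqrt(pi)/2) c_D sqrt(-i omega).  The sinuosity xi >= 1 of
the skeleton rescales everything by 1/xi^2; all per-axon statistics are taken
along arc length ("stretched" axon) before that rescaling.

Beyond short-range disorder, a structural spectrum Gamma_eta(q) ~ C |q|^p at
q -> 0 produces power-law tails t^-theta with the dynamical exponent
theta = (p + 1)/2; the closed forms for the instantaneous, dispersive and
cumulative tails are implemented for any p > -1 (the cumulative branch
requires theta < 1, otherwise the 1/t contributions it neglects dominate).

Inverse direction: measured (D_inf, c_D) map back to (<1/alpha>, Gamma_0),
which is how a dMRI measurement is read as axon morphology.

Units: um, ms, um^2/ms; c_D in um^2 ms^-1/2; Gamma_0 in um.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import IntegrationWarning, quad
from scipy.special import gamma as euler_gamma

from .geometry import RelativeProfile
from .spectral import SpectralDensity

__all__ = [
    "DEFAULT_D0",
    "DiffusionParams",
    "PowerLawSpectrum",
    "DtCurve",
    "predict_dinf",
    "predict_cd",
    "dt_asymptote",
    "dispersive_diffusivity",
    "tail_from_spectrum",
    "powerlaw_tails",
    "invert_to_geometry",
    "bead_model_gamma0",
    "write_dt_curve",
    "read_dt_curve",
]

#: Intrinsic axoplasmic diffusivity in um^2/ms (overridable everywhere).
DEFAULT_D0 = 2.0


@dataclass
class DtCurve:
    """A sampled diffusion-coefficient curve, cumulative D(t) or instantaneous."""

    t: np.ndarray              # ms, positive ascending
    D: np.ndarray              # um^2/ms
    sd: np.ndarray | None = None
    kind: str = "cumulative"   # "cumulative" | "instantaneous"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.t <= 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be positive ascending")
        if self.t.shape != self.D.shape:
            raise ValueError("t and D must have equal shapes")
        if self.kind not in ("cumulative", "instantaneous"):
            raise ValueError("kind must be 'cumulative' or 'instantaneous'")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass
class DiffusionParams:
    """The (D0, D_inf, c_D, xi) parameter set with derived geometry.

    ``tortuosity`` and ``gamma0`` are optional; when populated they must be
    consistent with the diffusion fields:
    tortuosity = D0/(xi^2 D_inf) and c_D = 2 Gamma_0 sqrt(D_inf xi^2/pi)/xi^2.
    """

    D0: float
    Dinf: float
    cD: float
    xi: float = 1.0
    tortuosity: float | None = None
    gamma0: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.Dinf <= self.D0):
            raise ValueError("require 0 < Dinf <= D0")
        if self.cD < 0:
            raise ValueError("cD must be nonnegative")
        if self.xi < 1:
            raise ValueError("sinuosity xi must be >= 1")
        if self.tortuosity is not None:
            expect = self.D0 / (self.xi**2 * self.Dinf)
            if abs(self.tortuosity - expect) > 1e-10 * expect:
                raise ValueError("tortuosity inconsistent with D0/(xi^2 Dinf)")
        if self.gamma0 is not None:
            expect = 2.0 * self.gamma0 * math.sqrt(self.Dinf * self.xi**2 / math.pi) / self.xi**2
            tol = 1e-10 * max(expect, 1e-30)
            if abs(self.cD - expect) > tol:
                raise ValueError("cD inconsistent with 2 Gamma0 sqrt(Dinf xi^2/pi)/xi^2")

    @classmethod
    def from_geometry(
        cls,
        rel: RelativeProfile,
        gamma0: float,
        D0: float = DEFAULT_D0,
        xi: float = 1.0,
    ) -> "DiffusionParams":
        """Forward map: profile statistics -> diffusion parameters."""
        tort = float(np.mean(1.0 / rel.alpha))
        dinf = D0 / (tort * xi**2)
        cd = predict_cd(gamma0, dinf * xi**2, xi)
        return cls(D0=D0, Dinf=dinf, cD=cd, xi=xi, tortuosity=tort, gamma0=gamma0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"D0_um2_per_ms": self.D0, "Dinf_um2_per_ms": self.Dinf,
                 "cD_um2_per_sqrt_ms": self.cD, "xi": self.xi,
                 "tortuosity": self.tortuosity, "gamma0_um": self.gamma0},
                fh, indent=2,
            )


@dataclass
class PowerLawSpectrum:
    """Structural spectrum Gamma_eta(q) ~= C |q|^p as q -> 0."""

    exponent: float            # p, dimensionless, > -1
    amplitude: float           # C, um^(1+p)

    def __post_init__(self) -> None:
        if self.exponent <= -1:
            raise ValueError("p must exceed -1 for an integrable spectrum")

    @property
    def theta(self) -> float:
        """Dynamical exponent theta = (p + 1)/2 of the t^-theta tail."""
        return (self.exponent + 1.0) / 2.0


def predict_dinf(rel: RelativeProfile, D0: float = DEFAULT_D0, xi: float = 1.0) -> float:
    """Long-time diffusivity D_inf = D0 / (<1/alpha> xi^2)."""
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if xi < 1:
        raise ValueError("xi must be >= 1")
    return D0 / (float(np.mean(1.0 / rel.alpha)) * xi**2)


def predict_cd(gamma0: float, Dinf_l: float, xi: float = 1.0) -> float:
    """Tail amplitude c_D = 2 Gamma_0 sqrt(Dinf_l/pi) / xi^2.

    ``Dinf_l`` is the stretched-axon (arc-length) long-time diffusivity before
    sinuosity rescaling, i.e. Dinf_l = D_inf * xi^2.
    """
    if gamma0 < 0:
        raise ValueError("gamma0 must be nonnegative")
    if Dinf_l <= 0:
        raise ValueError("Dinf_l must be positive")
    return 2.0 * gamma0 * math.sqrt(Dinf_l / math.pi) / xi**2


def dt_asymptote(params: DiffusionParams, times: np.ndarray) -> DtCurve:
    """The asymptotic cumulative curve D(t) = D_inf + c_D/sqrt(t)."""
    t = np.asarray(times, dtype=float)
    return DtCurve(t=t, D=params.Dinf + params.cD / np.sqrt(t), kind="cumulative")


def dispersive_diffusivity(params: DiffusionParams, omega) -> np.ndarray:
    """Complex dispersive diffusivity D(omega) = D_inf + (sqrt(pi)/2) c_D sqrt(-i omega).

    The square-root branch is sqrt(-i omega) = sqrt(omega/2) (1 - i) for
    omega >= 0, so that Re D(omega) = D_inf + sqrt(pi/8) c_D sqrt(omega) >= D_inf.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be nonnegative")
    root = np.sqrt(w / 2.0) * (1.0 - 1.0j)
    return params.Dinf + (math.sqrt(math.pi) / 2.0) * params.cD * root


def _spectrum_callable(spec) -> tuple:
    """Return (Gamma(k) callable, k_support_max or None)."""
    if callable(spec):
        return spec, None
    if isinstance(spec, SpectralDensity):
        q, g = spec.q, spec.gamma
        qmax = float(q[-1])

        def gamma_k(k):
            return np.interp(k, q, g, left=g[0], right=0.0)

        return gamma_k, qmax
    raise TypeError("spec must be a SpectralDensity or a callable Gamma(k)")


def tail_from_spectrum(
    spec,
    Dinf: float,
    times: np.ndarray,
    rtol: float = 1e-6,
) -> tuple[DtCurve, DtCurve]:
    """Diffusivity corrections from an arbitrary structural spectrum.

    Evaluates, by adaptive quadrature over wavevector k,

        delta_D_inst(t)/D_inf = int dk/2pi Gamma(k) (1 + 2 D k^2 t) e^{-D k^2 t}

    and its running time-average delta_D(t) = (1/t) int_0^t delta_D_inst dt',
    whose k-integrand is Gamma(k) [3 - (3 + 2u) e^{-u}]/u with u = D k^2 t
    (the t' integral done in closed form).  Returns (instantaneous,
    cumulative) curves of the *corrections* delta_D; for a flat spectrum the
    long-t limits are Gamma_0 sqrt(D/(pi t)) and 2 Gamma_0 sqrt(D/(pi t)).
    """
    if Dinf <= 0:
        raise ValueError("Dinf must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    gamma_k, support = _spectrum_callable(spec)

    k_max = 20.0 / math.sqrt(Dinf * t.min())
    if support is not None:
        k_max = min(k_max, support)

    d_inst = np.empty_like(t)
    d_cum = np.empty_like(t)
    for i, ti in enumerate(t):
        a = Dinf * ti

        def f_inst(k):
            u = a * k * k
            return gamma_k(k) * (1.0 + 2.0 * u) * math.exp(-u)

        def f_cum(k):
            u = a * k * k
            if u < 1e-12:
                frac = 1.0 + 0.5 * u
            else:
                frac = (-3.0 * math.expm1(-u) - 2.0 * u * math.exp(-u)) / u
            return gamma_k(k) * frac

        # empirical spectra are piecewise linear: subdivision-limit warnings
        # from the adaptive quadrature are expected and benign at this rtol
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IntegrationWarning)
            val, _ = quad(f_inst, 0.0, k_max, epsrel=rtol, limit=200)
            d_inst[i] = Dinf * val / math.pi      # two-sided k integral
            # the cumulative integrand decays only as 1/k^2: integrate to the
            # end of the spectrum's support, or to infinity for a callable
            upper = support if support is not None else np.inf
            val, _ = quad(f_cum, 0.0, upper, epsrel=rtol, limit=400,
                          points=[k_max] if np.isfinite(upper) else None)
            d_cum[i] = Dinf * val / math.pi
    return (
        DtCurve(t=t, D=d_inst, kind="instantaneous"),
        DtCurve(t=t, D=d_cum, kind="cumulative"),
    )


def powerlaw_tails(
    spec: PowerLawSpectrum,
    Dinf: float,
    times: np.ndarray | None = None,
    omega: np.ndarray | None = None,
) -> dict:
    """Closed-form power-law tails for a structural exponent p.

    Returns a dict with whichever of the following were requested:
    ``d_inst`` and ``d_cum`` (DtCurve corrections, from ``times``) and
    ``d_dispersive`` (complex ndarray, from ``omega``).  The cumulative tail
    is only defined for theta < 1 and raises otherwise (faster tails are
    overtaken by the 1/t term that this asymptote neglects).
    """
    if Dinf <= 0:
        raise ValueError("Dinf must be positive")
    th = spec.theta
    C = spec.amplitude
    out: dict = {"theta": th}
    if times is not None:
        t = np.asarray(times, dtype=float)
        coeff = (1.0 + 2.0 * th) * euler_gamma(th) / (2.0 * math.pi)
        inst = Dinf * coeff * C / (Dinf * t) ** th
        out["d_inst"] = DtCurve(t=t, D=inst, kind="instantaneous")
        if th < 1.0:
            out["d_cum"] = DtCurve(t=t, D=inst / (1.0 - th), kind="cumulative")
        else:
            out["d_cum"] = None
    if omega is not None:
        w = np.asarray(omega, dtype=float)
        pref = Dinf * (1.0 + 2.0 * th) * C / (2.0 * math.sin(math.pi * th))
        out["d_dispersive"] = pref * ((-1.0j * w) / Dinf) ** th
    return out


def cumulative_tail_or_raise(spec: PowerLawSpectrum, Dinf: float, times) -> DtCurve:
    """The cumulative-D(t) tail, rejecting theta >= 1 with the validity note."""
    if spec.theta >= 1.0:
        raise ValueError(
            "cumulative D(t) tail undefined for theta >= 1 (p >= 1): the "
            "asymptote is only valid for sufficiently slow tails; a 1/t term "
            "dominates otherwise"
        )
    return powerlaw_tails(spec, Dinf, times=times)["d_cum"]


def invert_to_geometry(
    Dinf_meas: float,
    cD_meas: float,
    D0: float = DEFAULT_D0,
    xi: float = 1.0,
) -> tuple[float, float]:
    """Invert (D_inf, c_D) to the morphological plane (<1/alpha>, Gamma_0).

    <1/alpha> = D0/(xi^2 D_inf);  Gamma_0 = c_D xi / (2 sqrt(D_inf/pi)).
    Exact algebraic inverse of (predict_dinf, predict_cd).
    """
    if not (0 < Dinf_meas <= D0):
        raise ValueError("require 0 < Dinf <= D0 (tortuosity >= 1)")
    if cD_meas < 0:
        raise ValueError("cD must be nonnegative")
    if xi < 1:
        raise ValueError("xi must be >= 1")
    tort = D0 / (xi**2 * Dinf_meas)
    gamma0 = cD_meas * xi / (2.0 * math.sqrt(Dinf_meas / math.pi))
    return tort, gamma0


def bead_model_gamma0(mean_spacing: float, sd_spacing: float, bead_fraction: float) -> float:
    """Single-bead-model plateau Gamma_0 = (sigma_a^2 / abar) phi^2.

    Identical multiplicative beads at renewal positions with interval mean
    ``abar`` and SD ``sigma_a``; ``phi`` is the dimensionless bead fraction
    (integral of one bead's eta profile over abar).
    """
    if mean_spacing <= 0:
        raise ValueError("mean spacing must be positive")
    if sd_spacing < 0:
        raise ValueError("spacing SD must be nonnegative")
    return (sd_spacing**2 / mean_spacing) * bead_fraction**2


def write_dt_curve(curve: DtCurve, path) -> None:
    data = {"t_ms": curve.t, "D_um2_per_ms": curve.D}
    if curve.sd is not None:
        data["sd"] = curve.sd
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_dt_curve(path, kind: str = "cumulative") -> DtCurve:
    df = pd.read_csv(path, sep="\t", comment="#")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return DtCurve(
        t=df["t_ms"].to_numpy(dtype=float),
        D=df["D_um2_per_ms"].to_numpy(dtype=float),
        sd=sd,
        kind=kind,
    )
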