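"""Fick-Jacobs diffusion in a tube of varying cross-section.

The 1-D dynamics d_t psi = D0 d_x [A(x) d_x (psi/A)] is discretized by finite
volumes on the profile grid: the hop rate between neighboring sites is
k_{j->j+1} = D0 * A_interface / (A_j dl^2) with a geometric-mean interface
area, which satisfies detailed balance exactly with the stationary measure
pi_j proportional to A_j (spins fill volume).  The profile is extended with
its mirror image ("reflective copy") into a ring of period 2L, so walkers see
no geometric discontinuity; displacements are tracked unwrapped.

Two engines share this generator:

* ``simulate_walkers`` — discrete-time Monte Carlo hops (numba kernel, one
  independent RNG stream per walker derived from the master seed);
* ``solve_msd_exact`` — a deterministic spectral solution of the same master
  equation with equilibrium (pi ~ A) starts, used as the oracle for small
  instances.

The choice of initial walker density matters for the time-dependent part of
D(t): a uniform-in-x start corresponds to the propagator of the 1-D density
psi and carries the full 1/sqrt(t) tail of the scattering theory, while an
equilibrium (volume-weighted) start halves that tail amplitude; both give
the same D_inf.  ``simulate_walkers`` defaults to the uniform convention.

MSD, cumulative D(t) = MSD/2t, and a finite-difference instantaneous
D_inst(t) are reported on a common time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import eigh_tridiagonal

from .geometry import AxonProfile

__all__ = [
    "REFERENCE_STEP_DURATION",
    "step_length_3d",
    "WalkerConfig",
    "SimResult",
    "FJGenerator",
    "build_generator",
    "simulate_walkers",
    "solve_msd_exact",
    "default_report_times",
]

#: Step duration (ms) used by the reference 3-D Monte Carlo protocol.
REFERENCE_STEP_DURATION = 8.74e-5


def step_length_3d(D0: float = 2.0, dt: float = REFERENCE_STEP_DURATION) -> float:
    """Isotropic 3-D random-walk step length sqrt(6 D0 dt) in um."""
    return math.sqrt(6.0 * D0 * dt)


def default_report_times(t_min: float = 1.0, t_max: float = 500.0, n: int = 64) -> np.ndarray:
    """64 log-spaced report times in [1, 500] ms by default."""
    return np.geomspace(t_min, t_max, n)


@dataclass
class WalkerConfig:
    D0: float = 2.0
    step_duration: float | None = None       # ms; None -> auto per profile
    n_walkers: int = 20000
    t_max: float = 500.0
    report_times: np.ndarray | None = None
    seed: int = 0
    initialization: str = "uniform"          # "uniform" | "equilibrium" (pi ~ A)

    def __post_init__(self) -> None:
        if self.n_walkers < 100:
            raise ValueError("need >= 100 walkers")
        if self.initialization not in ("equilibrium", "uniform"):
            raise ValueError("initialization must be 'equilibrium' or 'uniform'")
        if self.report_times is None:
            self.report_times = default_report_times(t_max=self.t_max)
        self.report_times = np.asarray(self.report_times, dtype=float)


@dataclass
class SimResult:
    times: np.ndarray        # ms
    msd: np.ndarray          # um^2
    D_cum: np.ndarray        # um^2/ms
    D_inst: np.ndarray       # um^2/ms
    se: np.ndarray           # standard error of D_cum (zeros for exact engine)
    n_walkers: int
    seed: int
    engine: str              # "walker" | "exact"

    def to_curve(self, kind: str = "cumulative"):
        from .theory import DtCurve

        values = self.D_cum if kind == "cumulative" else self.D_inst
        return DtCurve(t=self.times, D=values, sd=self.se.copy(), kind=kind)

    def to_table(self, path) -> None:
        pd.DataFrame(
            {"t_ms": self.times, "msd_um2": self.msd,
             "D_um2_per_ms": self.D_cum, "se": self.se}
        ).to_csv(path, sep="\t", index=False, float_format="%.9g")


class FJGenerator:
    """Transition rates of the FJ master equation on the mirrored-tiled ring."""

    def __init__(self, profile: AxonProfile, D0: float = 2.0, interface: str = "geometric"):
        if D0 <= 0:
            raise ValueError("D0 must be positive")
        if interface not in ("geometric", "harmonic"):
            raise ValueError("interface must be 'geometric' or 'harmonic'")
        a = profile.areas
        self.a_half = a                          # original half, N sites
        self.a_ring = np.concatenate([a, a[::-1]])
        self.dl = profile.dl
        self.D0 = D0
        self.M = self.a_ring.size
        self.interface = interface
        nxt = np.roll(self.a_ring, -1)
        if interface == "geometric":
            a_if = np.sqrt(self.a_ring * nxt)
        else:
            a_if = 2.0 * self.a_ring * nxt / (self.a_ring + nxt)
        # a_if[j] is the interface between j and j+1 (ring-wise)
        self.k_plus = D0 * a_if / (self.a_ring * self.dl**2)
        self.k_minus = D0 * np.roll(a_if, 1) / (self.a_ring * self.dl**2)

    @property
    def stationary(self) -> np.ndarray:
        """Equilibrium occupation pi_j ~ A_j, normalized on the ring."""
        return self.a_ring / self.a_ring.sum()

    def detailed_balance_residual(self) -> float:
        pi = self.stationary
        flux_r = pi * self.k_plus
        flux_l = np.roll(pi * self.k_minus, -1)
        return float(np.max(np.abs(flux_r - flux_l)) / np.max(flux_r))

    def max_step_duration(self) -> float:
        """Largest dt with per-direction hop probability <= 0.5."""
        return 0.5 / float(np.max(np.maximum(self.k_plus, self.k_minus)))

    def default_step_duration(self) -> float:
        """dt = 0.2 dl^2 / (D0 max(A_if/A)): total hop probability <= 0.4."""
        ratio = float(np.max(np.maximum(self.k_plus, self.k_minus))) * self.dl**2 / self.D0
        return 0.2 * self.dl**2 / (self.D0 * ratio)

    def dense_generator(self) -> np.ndarray:
        """Dense generator matrix (columns sum to zero); for small instances."""
        G = np.zeros((self.M, self.M))
        idx = np.arange(self.M)
        G[(idx + 1) % self.M, idx] += self.k_plus
        G[(idx - 1) % self.M, idx] += self.k_minus
        G[idx, idx] -= self.k_plus + self.k_minus
        return G


def build_generator(profile: AxonProfile, D0: float = 2.0,
                    interface: str = "geometric") -> FJGenerator:
    """Finite-volume transition-rate structure for a profile (see FJGenerator)."""
    return FJGenerator(profile, D0=D0, interface=interface)


@njit(cache=True)
def _walk_kernel(p_right, p_left, start, n_steps, report_steps, sum_d2, sum_d4, seed):
    """Discrete-time hops on the ring; per-walker xorshift64* streams.

    Accumulates sum of squared and fourth-power displacements (lattice units)
    at each report step.
    """
    M = p_right.shape[0]
    nw = start.shape[0]
    nr = report_steps.shape[0]
    inv64 = 1.0 / 18446744073709551616.0
    for w in range(nw):
        # splitmix64: derive an independent, well-mixed state per walker
        z = seed + np.uint64(w + 1) * np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state = z ^ (z >> np.uint64(31))
        if state == np.uint64(0):
            state = np.uint64(0x9E3779B97F4A7C15)
        j = start[w]
        x = 0
        ri = 0
        for s in range(n_steps):
            state ^= state >> np.uint64(12)
            state ^= state << np.uint64(25)
            state ^= state >> np.uint64(27)
            u = float(state * np.uint64(0x2545F4914F6CDD1D)) * inv64
            if u < p_right[j]:
                x += 1
                j += 1
                if j == M:
                    j = 0
            elif u < p_right[j] + p_left[j]:
                x -= 1
                j -= 1
                if j < 0:
                    j = M - 1
            if ri < nr and s + 1 == report_steps[ri]:
                d2 = float(x) * x
                sum_d2[ri] += d2
                sum_d4[ri] += d2 * d2
                ri += 1


def simulate_walkers(profile: AxonProfile, config: WalkerConfig) -> SimResult:
    """Monte Carlo random walkers on the mirrored-tiled FJ lattice.

    Hop probabilities are k * dt; displacement is tracked unwrapped across
    the periodic images.  The default uniform-in-x initialization reproduces
    the disorder-averaged propagator statistics that the closed-form
    (D_inf, c_D) theory describes; ``initialization='equilibrium'`` starts
    from pi ~ A (volume-weighted spins), which leaves D_inf and the tail
    exponent intact but halves the 1/sqrt(t) tail amplitude.
    """
    gen = build_generator(profile, D0=config.D0)
    dt = config.step_duration if config.step_duration is not None else gen.default_step_duration()
    p_right = gen.k_plus * dt
    p_left = gen.k_minus * dt
    pmax = float(np.max(np.maximum(p_right, p_left)))
    if pmax > 0.5:
        raise ValueError(
            f"hop probability {pmax:.3f} > 0.5 at step_duration = {dt:.3g} ms; "
            f"maximal admissible step_duration is {gen.max_step_duration():.3g} ms"
        )

    report = np.asarray(config.report_times, dtype=float)
    report_steps = np.unique(np.maximum(np.rint(report / dt).astype(np.int64), 1))
    times = report_steps * dt

    rng = np.random.default_rng(config.seed)
    if config.initialization == "equilibrium":
        start = rng.choice(gen.M, size=config.n_walkers, p=gen.stationary)
    else:
        start = rng.integers(0, gen.M, size=config.n_walkers)
    start = start.astype(np.int64)

    sum_d2 = np.zeros(report_steps.size)
    sum_d4 = np.zeros(report_steps.size)
    master = np.uint64(np.random.SeedSequence(config.seed).generate_state(1, np.uint64)[0])
    _walk_kernel(p_right, p_left, start, int(report_steps[-1]), report_steps,
                 sum_d2, sum_d4, master)

    nw = config.n_walkers
    msd = sum_d2 / nw * gen.dl**2
    var_d2 = sum_d4 / nw * gen.dl**4 - msd**2
    se_msd = np.sqrt(np.maximum(var_d2, 0.0) / nw)
    d_cum = msd / (2.0 * times)
    d_inst = np.gradient(msd, times) / 2.0
    return SimResult(
        times=times, msd=msd, D_cum=d_cum, D_inst=d_inst,
        se=se_msd / (2.0 * times), n_walkers=nw, seed=config.seed, engine="walker",
    )


_MAX_EXACT_SITES = 8192          # ring sites after mirroring


def solve_msd_exact(profile: AxonProfile, D0: float, times: np.ndarray) -> SimResult:
    """Deterministic MSD of the FJ master equation on the mirrored ring.

    The pi-symmetrized generator H has constant off-diagonal D0/dl^2 (a
    property of the geometric-mean interface) and commutes with the mirror
    reflection of the ring.  The displacement source vector is odd under that
    reflection, so only the odd-sector modes contribute; that sector is an
    N x N symmetric tridiagonal eigenproblem.  With eigenpairs (lambda_n, c_n),

        MSD(t) = c0 t - 2 sum_n c_n^2 [ (e^{lambda_n t} - 1)/lambda_n^2
                                         - t/lambda_n ],

    where c0 = dl^2 sum_j pi_j (k+_j + k-_j) is the free short-time slope.
    Valid while the diffusion length stays below 1/8 of the ring period.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    gen = build_generator(profile, D0=D0, interface="geometric")
    if gen.M > _MAX_EXACT_SITES:
        raise ValueError(
            f"mirrored lattice has {gen.M} sites; exact solver limited to "
            f"{_MAX_EXACT_SITES} (use simulate_walkers for larger profiles)"
        )
    period = gen.M * gen.dl
    t_valid = (period / 8.0) ** 2 / (2.0 * D0)
    if times.max() > t_valid:
        raise ValueError(
            f"requested t = {times.max():.3g} ms exceeds the diffusion-length "
            f"bound (length <= period/8): t must stay below {t_valid:.3g} ms"
        )

    N = gen.M // 2
    dl = gen.dl
    b = D0 / dl**2
    diag = -(gen.k_plus + gen.k_minus)[:N].copy()
    # odd sector under the mirror j <-> M-1-j: boundary couplings flip sign
    diag[0] -= b
    diag[N - 1] -= b
    off = np.full(N - 1, b)
    lam, vec = eigh_tridiagonal(diag, off)

    pi = gen.stationary
    s_tilde = np.sqrt(pi[:N]) * dl * (gen.k_minus - gen.k_plus)[:N]
    c = math.sqrt(2.0) * vec.T @ s_tilde          # overlaps in the odd sector
    c0 = dl**2 * float(np.sum(pi * (gen.k_plus + gen.k_minus)))

    lt = lam[None, :] * times[:, None]
    with np.errstate(over="ignore"):
        decay = np.where(lt < -700, 0.0, np.exp(lt))
    term = (decay - 1.0) / lam[None, :] ** 2 - times[:, None] / lam[None, :]
    msd = c0 * times - 2.0 * (term @ (c**2))

    d_cum = msd / (2.0 * times)
    d_inst = np.gradient(msd, times) / 2.0
    return SimResult(
        times=times, msd=msd, D_cum=d_cum, D_inst=d_inst,
        se=np.zeros_like(times), n_walkers=0, seed=0, engine="exact",
    )
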