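# Methods

## The model

Water diffusing along the interior of an axon sees a tube whose
cross-sectional area `A(l)` fluctuates along the arc length `l` (beads,
varicosities, constrictions).  Once the molecules have equilibrated across
the cross-section (times beyond ~1 ms for micrometer-caliber axons), the
3-D problem reduces to one-dimensional Fick–Jacobs dynamics for the linear
density `psi(t, l)`:

    d_t psi = D0 d_l [ A(l) d_l (psi / A(l)) ],

with `D0` the intrinsic axoplasmic diffusivity.  The quantity dMRI can reach
is the along-axon diffusion coefficient `D(t) = <x^2(t)>/2t`.  For
*short-range* structural disorder — finite correlation length, so the power
spectral density of `eta(l) = ln alpha(l)`, `alpha = A/<A>`, has a finite
plateau `Gamma_0 = Gamma_eta(q -> 0)` — the long-time behavior is

    D(t) ~= D_inf + c_D / sqrt(t),
    D0 / D_inf = <1/alpha>,              (exact tortuosity limit)
    c_D = 2 Gamma_0 sqrt(D_inf / pi),

and in the frequency domain `D(omega) ~= D_inf + (sqrt(pi)/2) c_D
sqrt(-i omega)`.  Two numbers — the mean reciprocal relative cross-section
`<1/alpha>` and the large-scale fluctuation strength `Gamma_0` (units of
length) — summarize the entire random geometry.  Inverting the two relations
maps a measured `(D_inf, c_D)` back onto `(<1/alpha>, Gamma_0)`, which is
how a macroscopic measurement becomes a morphological readout.

For general structural spectra `Gamma_eta(q) ~ C |q|^p` the tail exponent is
`theta = (p+1)/2`; the package implements the closed forms for the
instantaneous, cumulative, and dispersive corrections for any `p > -1`, with
the cumulative form restricted to `theta < 1` where it dominates the `1/t`
contributions it neglects.  Skeleton undulations enter only through the
sinuosity `xi >= 1` (arc over Euclidean length), which rescales the whole
curve by `1/xi^2`; all cross-sectional statistics are taken along arc length
first and rescaled per axon afterwards.

## Initialization and the tail amplitude

A point the closed forms leave implicit is *which ensemble of walkers* the
`1/sqrt(t)` tail describes.  The scattering treatment works with the
disorder-averaged propagator of `psi`, i.e. trajectories launched from a
delta in `psi` — walkers placed uniformly in `l`, irrespective of the local
cross-section.  Three independent routes in this package (the spectral
master-equation solver, a continuous-space Langevin integration used during
development, and the lattice Monte Carlo engine) agree that:

* with **uniform-in-l** starts, the simulated `D(t)` matches the full
  spectral quadrature and the flat-spectrum tail `c_D = 2 Gamma_0
  sqrt(D_inf/pi)` within Monte Carlo error at all times;
* with **equilibrium** starts (`pi ~ A`, spins proportional to volume), the
  asymptotic cumulative tail amplitude is `Gamma_0 sqrt(D_inf/pi)` — exactly
  half — while `D_inf` and the exponent are unchanged.

`simulate_walkers` therefore defaults to the uniform convention, which is
the regime the closed forms describe; `initialization="equilibrium"` is
available, and a regression test pins the fact that the two differ.  In
practice the distinction is hard to see in window-limited fits: over a
`[10, 500]` ms fit window the early-time transient contributes extra
apparent slope that largely compensates the halved asymptote, so fitted
`c_D` values land near the full-amplitude prediction for either convention.

## Finite-window effects on fitted tail parameters

The asymptote assumes coarse-graining past the disorder correlation length
`l_c`.  Beads of width `sigma_1 ~ 3-7 um` give a correlation time
`t_c ~ sigma_1^2 / D_inf ~ 5-25 ms`, and the *cumulative* coefficient
retains an `O(sqrt(t_c/t))` deficit long after the instantaneous one has
converged (the cumulative average keeps integrating over the early
transient).  Consequently, over `t in [50, 500]` ms the effective log-log
exponent of `D(t) - D_inf` for the default bead geometry is ~0.40-0.45
rather than the asymptotic 0.5, and window-fitted `c_D` sits below the
plateau prediction; both converge from below as the window moves to larger
`t / t_c`.  Single-profile comparisons add two stochastic scatters on top:
Monte Carlo noise in the fitted slope (about 0.04-0.1 at 2e4 walkers) and
plateau-estimation noise (the lowest periodogram bins are
exponential-distributed; roughly 10-30% on `Gamma_0` at `L = 2 mm`).
Ensemble averaging over profiles — which is also what a dMRI voxel does —
is the appropriate way to validate the tail amplitude; the acceptance
checks use a five-profile ensemble for that reason.

## Numerical design

**Discretization.**  Finite volumes on the arc-length grid (spacing `dl`,
default 0.1 um): hop rates `k_{j->j+1} = D0 A_interface / (A_j dl^2)` with a
geometric-mean interface area.  This choice makes the pi-symmetrized
generator have constant off-diagonal `D0/dl^2` (the disorder becomes purely
diagonal) and satisfies detailed balance with `pi ~ A` exactly.  A harmonic
interface mean is available as an option.  The profile is extended with its
mirror image into a ring of period `2L` so walkers cross the ends without
geometric discontinuity; displacements are unwrapped through the periodic
images.

**Walker engine.**  Discrete-time hops with per-direction probability
`k dt`; the default step `dt = 0.2 dl^2 / (D0 max(A_if/A))` keeps total hop
probability at 0.4 (steps with probability above 0.5 are rejected with the
admissible bound).  Each walker owns an independent xorshift64* stream
seeded from the master seed via splitmix64, so results are bitwise
reproducible for a given seed at any walker count.  The reference step
duration of the 3-D protocol this emulates (8.74e-5 ms, step length
0.0324 um at `D0 = 2 um^2/ms`) is kept as a documented constant.

**Exact solver.**  For small instances the master equation is solved
spectrally.  The mirrored ring commutes with its reflection; the
displacement source vector is odd under it, so only the odd sector
contributes to the stationary-start MSD, and that sector is an `N x N`
symmetric tridiagonal eigenproblem — seconds at `N = 3000`, validated
against a dense full-ring eigendecomposition and against the walker engine.
The closed form is

    MSD(t) = c0 t - 2 sum_n c_n^2 [ (e^{lambda_n t} - 1)/lambda_n^2
                                     - t/lambda_n ],

with `c0` the free short-time slope and `c_n` the overlaps of the source
with the odd modes.  The solver assumes equilibrium starts (the formula
uses stationarity of the occupation) and enforces a diffusion-length bound
`sqrt(2 D0 t) <= period/8` plus a size cap of ~8000 ring sites.

**Spectral estimation.**  Plain periodogram with the continuum
normalization `Gamma = |eta_q|^2 / L` (`eta_q = sum eta_j e^{-iql_j} dl`,
`L = N dl`), mean subtracted, no taper; optional non-overlapping segment
averaging.  Parseval holds exactly over the two-sided grid.  The plateau is
the mean of `Gamma` over the lowest bins, where the cutoff is swept so the
excluded high-`q` bins carry fractions `beta in {0.92 ... 0.97}` of the
spectral variance; the mean and SD over the sweep give `Gamma_0` and its
uncertainty, with a floor of three bins (flagged when forced).  The exact
cutoff rule is a convention of this package; treat it as tunable.

**Quadrature.**  The spectral tail integral is evaluated adaptively in `k`
(rtol 1e-6).  The cumulative correction integrates the time average in
closed form under the `k` integral, `[3 - (3+2u) e^{-u}]/u` with
`u = D_inf k^2 t`, evaluated with `expm1` for small `u`; because that
integrand decays only as `1/k^2`, the integral runs to the end of the
spectrum's support (or to infinity for analytic spectra).

**Fitting.**  `D` against `1/sqrt(t)` by unweighted OLS (inverse-variance
weighting optional), central window `[10, 500]` ms; the reported parameter
uncertainties are the spread over refits with the lower bound swept through
`t0 in [3, 10]` ms — a model-range uncertainty, not a within-fit standard
error.  `sigma_D(t) = sqrt(sigma_Dinf^2 + sigma_cD^2/t)` propagates them to
a curve.

## Synthetic data

`generate_bead_profile` renders `A(l) = A0 + sum_m A1 G_{sigma1}(l - l_m)`
with unit-mass Gaussian beads at renewal positions whose gaps are
`Normal(abar, sigma_a^2)` truncated below at `2 dl` (the truncation rule for
near-zero gaps is a convention; achieved moments are recorded, and a
rejection fraction above 50% warns).  The generator works on a padded
domain (5 kernel widths plus 5 spacings per side) and crops, so bead
density carries no edge dilution.  Parameter ranges follow the reference
protocol: `A0 = pi (0.5)^2 um^2`, `A1 in [0.1, 2.5] um^2`, `sigma1 in
[3, 7] um`, `abar in [3, 7] um`, `sigma_a in [0.8, 1.2] abar`.  The
single-profile defaults sit at the pronounced-beading end of these ranges
(`A1 = 2.5`, `sigma1 = 3`, `abar = 5`, `sigma_a = 6`): mid-range values,
once smoothed by the wide kernel, leave `var(alpha) ~ 0.006` — a tube whose
time dependence is an order of magnitude below what visibly beaded axons
show.  For small beads the plateau approaches the single-bead model
`Gamma_0 = (sigma_a^2/abar) phi^2` with bead fraction `phi = A1/(Abar
abar)`; the mapping is first-order in `A1` and is asserted only in that
regime.

`generate_spectrum_profile` synthesizes Gaussian random fields `eta` with
spectrum `C |q|^p e^{-(q l_c)^2}` by Fourier filtering, exponentiated to
`A = Abar e^eta` (positive by construction) — the probe for the power-law
universality classes.

What the generator does *not* emulate: real axons have finite length and
measurement noise in `A(l)`, cross-sections estimated from imperfect
segmentations, undulating skeletons (synthetic tubes are straight,
`xi = 1`), and spatially correlated pathology along a tract.  Passing tests
therefore demonstrate the internal consistency of theory, simulation, and
estimation on the generator's statistics — not segmentation robustness.

## Cohort statistics

Per-axon curves combine with volume weights `w_i ~ Abar_i L_i` (what spin
density does to a voxel signal).  Group contrasts use the nonparametric
effect size `d_eff = (median X - median Y)/PMAD`, where each group's MAD is
taken about its Hodges–Lehmann pseudo-median (median of all Walsh averages;
a plain-median variant sits behind a flag) and pooled with `n-1` weights.
No p-values are computed by design — at thousands of axons per group,
hypothesis tests reject for irrelevantly small shifts.  The 2-D separation
score fits a soft-margin linear SVM (C = 1) on robustly standardized
(median/MAD) coordinates after seeded subsampling of the larger group to
balance classes; every point's signed distance to the hyperplane is its
`z` score, oriented so the control group has the lower median.  Kernel,
regularization, and standardization are this package's choices.

## Problem sizes

Defaults used by the test-suite and the acceptance script: profiles of
300 um (deterministic solver) and 2000 um (walker validation) at
`dl = 0.1 um`; 2e4 walkers per profile, five-profile ensembles for tail
validation; 20 realizations for the single-bead plateau check; cohorts of
20 axons per group at 300 um.  These sizes put Monte Carlo standard errors
near 1% per curve point, which the acceptance tolerances reflect.

## Known limitations

* The Fick–Jacobs reduction assumes transverse equilibration; strongly
  beaded tubes where transverse and longitudinal dynamics do not decouple
  acquire corrections the 1-D engine cannot see.
* Cross-section estimation from images, 3-D voxel walkers, membrane
  permeability, exchange, relaxation weighting, and gradient-waveform
  signal synthesis are out of scope.
* The plateau estimator's variance-fraction cutoff is a convention;
  alternative low-`q` fitting rules shift `Gamma_0` within its quoted
  uncertainty for flat spectra but can differ materially for steep ones.
* Window-limited fits of `(D_inf, c_D)` retain the finite-`t_c` biases
  described above; they are properties of the estimation window, not of the
  asymptotic theory.
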