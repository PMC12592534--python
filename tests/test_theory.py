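import numpy as np
import pytest

from axodiff import geometry, theory
from axodiff.geometry import AxonProfile, relative_profile
from axodiff.theory import (
    DiffusionParams, DtCurve, PowerLawSpectrum, bead_model_gamma0,
    cumulative_tail_or_raise, dispersive_diffusivity, dt_asymptote,
    invert_to_geometry, powerlaw_tails, predict_cd, predict_dinf,
    tail_from_spectrum,
)


def two_level_rel():
    l = np.arange(0, 3.2, 0.1)
    return relative_profile(AxonProfile(l, np.tile([0.5, 1.5], 16)))


class TestForwardMaps:
    def test_uniform_tube(self, constant_profile):
        rel = relative_profile(constant_profile)
        assert predict_dinf(rel, D0=2.0, xi=1.0) == pytest.approx(2.0, rel=1e-12)

    def test_two_level(self):
        assert predict_dinf(two_level_rel(), D0=2.0) == pytest.approx(1.5, rel=1e-12)

    def test_sinuosity_rescaling(self):
        assert predict_dinf(two_level_rel(), D0=2.0, xi=1.02) == pytest.approx(
            1.5 / 1.0404, abs=1e-4
        )

    def test_cd_zero_plateau(self):
        assert predict_cd(0.0, 1.5) == 0.0

    def test_cd_closed_form(self):
        assert predict_cd(0.1, 1.5) == pytest.approx(0.2 * np.sqrt(1.5 / np.pi), abs=1e-5)
        assert predict_cd(0.1, 1.5) == pytest.approx(0.13820, abs=1e-5)

    def test_cd_linearity(self):
        assert predict_cd(0.2, 1.5) == pytest.approx(2 * predict_cd(0.1, 1.5), rel=1e-12)

    def test_dinf_never_exceeds_d0(self, rng):
        for _ in range(20):
            a = rng.lognormal(0, rng.uniform(0.05, 0.6), 128)
            rel = relative_profile(AxonProfile(np.arange(128) * 0.1, a))
            assert predict_dinf(rel, D0=2.0) <= 2.0 + 1e-12


class TestDtAsymptote:
    def test_constant_when_cd_zero(self):
        p = DiffusionParams(D0=2.0, Dinf=1.5, cD=0.0)
        curve = dt_asymptote(p, np.array([1.0, 10.0, 100.0]))
        np.testing.assert_allclose(curve.D, 1.5)

    def test_arithmetic_and_monotonicity(self):
        p = DiffusionParams(D0=2.0, Dinf=1.5, cD=0.138)
        curve = dt_asymptote(p, np.geomspace(1, 100, 32))
        assert curve.D[-1] == pytest.approx(1.5138, abs=1e-4)
        assert np.all(np.diff(curve.D) < 0)


class TestDispersive:
    def test_zero_frequency(self):
        p = DiffusionParams(D0=2.0, Dinf=1.5, cD=0.138)
        assert dispersive_diffusivity(p, 0.0) == pytest.approx(1.5)

    def test_real_part_branch_identity(self):
        # Re sqrt(-i w) = sqrt(w/2) so Re D = Dinf + sqrt(pi/8) cD sqrt(w)
        p = DiffusionParams(D0=2.0, Dinf=1.5, cD=0.138)
        for w in (0.01, 0.1, 1.0):
            z = dispersive_diffusivity(p, w)
            assert z.real == pytest.approx(1.5 + np.sqrt(np.pi / 8) * 0.138 * np.sqrt(w),
                                           rel=1e-12)
            assert z.real >= 1.5

    def test_numeric_value(self):
        p = DiffusionParams(D0=2.0, Dinf=1.5, cD=0.138)
        assert dispersive_diffusivity(p, 1.0).real == pytest.approx(
            1.5 + 0.6267 * 0.138, abs=1e-3
        )


class TestTailFromSpectrum:
    def test_zero_spectrum(self):
        inst, cum = tail_from_spectrum(lambda k: 0.0, 1.5, np.array([1.0, 10.0]))
        np.testing.assert_allclose(inst.D, 0.0, atol=1e-15)
        np.testing.assert_allclose(cum.D, 0.0, atol=1e-15)

    def test_flat_spectrum_closed_forms(self):
        # flat Gamma0: inst = Gamma0 sqrt(D/(pi t)); cum doubles it
        g0, dinf = 0.05, 1.5
        t = np.array([10.0, 100.0, 400.0])
        inst, cum = tail_from_spectrum(lambda k: g0, dinf, t)
        np.testing.assert_allclose(inst.D, g0 * np.sqrt(dinf / (np.pi * t)), rtol=0.01)
        np.testing.assert_allclose(cum.D, 2 * g0 * np.sqrt(dinf / (np.pi * t)), rtol=0.01)
        assert inst.D[1] == pytest.approx(0.003455, abs=4e-5)

    def test_lorentzian_approaches_flat_law(self):
        g0, lc, dinf = 0.05, 1.0, 1.5
        t = np.array([50.0, 200.0])  # t >> lc^2/Dinf
        inst, _ = tail_from_spectrum(lambda k: g0 / (1 + (k * lc) ** 2), dinf, t)
        np.testing.assert_allclose(inst.D, g0 * np.sqrt(dinf / (np.pi * t)), rtol=0.05)


class TestPowerLawTails:
    def test_theta_definition(self):
        assert PowerLawSpectrum(0.0, 1.0).theta == 0.5
        assert PowerLawSpectrum(1.0, 1.0).theta == 1.0
        with pytest.raises(ValueError):
            PowerLawSpectrum(-1.0, 1.0)

    def test_p0_reduces_to_short_range_forms(self):
        # p = 0, C = Gamma0: cumulative tail = cD/sqrt(t) with Eq-3 cD
        g0, dinf = 0.05, 1.5
        t = np.geomspace(1, 100, 7)
        out = powerlaw_tails(PowerLawSpectrum(0.0, g0), dinf, times=t)
        cd = 2 * g0 * np.sqrt(dinf / np.pi)
        np.testing.assert_allclose(out["d_cum"].D, cd / np.sqrt(t), rtol=1e-10)
        np.testing.assert_allclose(
            out["d_inst"].D, g0 * np.sqrt(dinf / (np.pi * t)), rtol=1e-10
        )

    def test_p0_dispersive_consistency(self):
        # delta D(omega) = Gamma0 sqrt(-i Dinf omega) for short-range disorder
        g0, dinf = 0.07, 1.8
        w = np.array([0.05, 0.5])
        out = powerlaw_tails(PowerLawSpectrum(0.0, g0), dinf, omega=w)
        np.testing.assert_allclose(
            out["d_dispersive"], g0 * np.sqrt(-1j * dinf * w), rtol=1e-10
        )

    def test_p0_matches_quadrature_at_long_t(self):
        g0, dinf = 0.05, 1.5
        t = np.array([200.0])
        inst, _ = tail_from_spectrum(lambda k: g0, dinf, t)
        out = powerlaw_tails(PowerLawSpectrum(0.0, g0), dinf, times=t)
        assert out["d_inst"].D[0] == pytest.approx(inst.D[0], rel=0.01)

    def test_p1_cumulative_rejected_instantaneous_kept(self):
        spec = PowerLawSpectrum(1.0, 0.02)
        t = np.array([10.0])
        with pytest.raises(ValueError, match="theta >= 1"):
            cumulative_tail_or_raise(spec, 1.5, t)
        out = powerlaw_tails(spec, 1.5, times=t)
        # theta = 1: coefficient 3 Gamma(1) / (2 pi) * C/(D t)
        assert out["d_inst"].D[0] == pytest.approx(
            1.5 * 3 / (2 * np.pi) * 0.02 / (1.5 * 10.0), rel=1e-10
        )
        assert out["d_cum"] is None

    def test_random_p_symbolic_consistency(self, rng):
        # Eq-24 instantaneous and cumulative differ by 1/(1 - theta) exactly
        for _ in range(10):
            p = rng.uniform(-0.9, 0.9)
            spec = PowerLawSpectrum(p, rng.uniform(0.01, 0.5))
            t = np.array([rng.uniform(5, 500)])
            out = powerlaw_tails(spec, rng.uniform(0.5, 2.5), times=t)
            assert out["d_cum"].D[0] == pytest.approx(
                out["d_inst"].D[0] / (1 - spec.theta), rel=1e-10
            )


class TestInversion:
    def test_trivial(self):
        assert invert_to_geometry(2.0, 0.0, D0=2.0) == (1.0, 0.0)

    def test_roundtrip_of_predict_example(self):
        tort, g0 = invert_to_geometry(1.5, 0.13820, D0=2.0)
        assert tort == pytest.approx(4.0 / 3.0, rel=1e-6)
        assert g0 == pytest.approx(0.1, abs=1e-4)

    def test_roundtrip_identity_random(self, rng):
        for _ in range(100):
            d0 = rng.uniform(1.0, 3.0)
            tort = rng.uniform(1.0, 2.0)
            g0 = rng.uniform(0.0, 0.5)
            xi = rng.uniform(1.0, 1.1)
            dinf = d0 / (tort * xi**2)
            cd = predict_cd(g0, dinf * xi**2, xi)
            tort_back, g0_back = invert_to_geometry(dinf, cd, D0=d0, xi=xi)
            assert tort_back == pytest.approx(tort, rel=1e-10)
            assert g0_back == pytest.approx(g0, rel=1e-10, abs=1e-12)

    def test_unphysical_rejected(self):
        with pytest.raises(ValueError):
            invert_to_geometry(2.5, 0.1, D0=2.0)


class TestBeadModel:
    def test_ordered_beads(self):
        assert bead_model_gamma0(5.0, 0.0, 0.2) == 0.0

    def test_closed_form(self):
        assert bead_model_gamma0(5.0, 5.0, 0.113) == pytest.approx(0.0638, abs=1e-4)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bead_model_gamma0(0.0, 1.0, 0.1)


class TestDiffusionParams:
    def test_consistency_enforced(self):
        with pytest.raises(ValueError, match="tortuosity"):
            DiffusionParams(D0=2.0, Dinf=1.5, cD=0.1, tortuosity=1.9)

    def test_from_geometry_consistency_chain(self):
        rel = two_level_rel()
        p = DiffusionParams.from_geometry(rel, gamma0=0.1, D0=2.0)
        assert p.Dinf == pytest.approx(1.5, rel=1e-12)
        assert p.cD == pytest.approx(predict_cd(0.1, 1.5), rel=1e-12)
        tort, g0 = invert_to_geometry(p.Dinf, p.cD, D0=2.0)
        assert tort == pytest.approx(p.tortuosity, rel=1e-12)
        assert g0 == pytest.approx(0.1, rel=1e-10)

    def test_curve_io_roundtrip(self, tmp_path):
        curve = DtCurve(t=np.geomspace(1, 100, 16), D=np.linspace(2, 1.5, 16))
        theory.write_dt_curve(curve, tmp_path / "c.tsv")
        back = theory.read_dt_curve(tmp_path / "c.tsv")
        np.testing.assert_allclose(back.D, curve.D, rtol=1e-8)
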