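import numpy as np
import pytest

from seqdbn import (
    BivariateVonMisesParams,
    KentParams,
    VonMisesParams,
    bvm_conditional,
    bvm_estimate,
    bvm_log_density,
    bvm_log_normalizer,
    bvm_sample,
    kent_estimate,
    kent_log_density,
    kent_log_normalizer,
    kent_sample,
    vm_estimate,
    vm_log_density,
    vm_sample,
    vmf_log_density,
)
from seqdbn.directional import _bvm_psi_marginal_log, kent_suff_stats
from seqdbn.errors import EstimationError, ParameterError

from ._oracles import (
    circle_integral,
    mc_sphere_log_normalizer,
    sphere_integral,
    torus_integral,
)

TWO_PI = 2 * np.pi


def _frame(seed=None):
    """An orthonormal FB5 frame (rows gamma1..3); default is axis-aligned."""
    if seed is None:
        return np.eye(3)[[2, 0, 1]]
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q.T


def _rand_units(n, rng):
    x = rng.standard_normal((n, 3))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


# ===========================================================================
# Univariate von Mises
# ===========================================================================

class TestVonMises:
    def test_uniform_limit(self):
        p = VonMisesParams(mu=1.0, kappa=1e-8)
        theta = np.linspace(0, TWO_PI, 64, endpoint=False)
        assert np.allclose(np.exp(vm_log_density(p, theta)), 1 / TWO_PI, atol=1e-6)

    def test_density_integrates_to_one(self):
        p = VonMisesParams(mu=2.0, kappa=50.0)
        assert circle_integral(lambda t: vm_log_density(p, t)) == pytest.approx(
            1.0, abs=1e-10)

    def test_estimate_recovers_parameters(self):
        rng = np.random.default_rng(4)
        p = VonMisesParams(mu=1.0, kappa=20.0)
        est = vm_estimate(vm_sample(p, 10_000, rng))
        assert abs(est.mu - 1.0) < 0.02
        assert abs(est.kappa - 20.0) / 20.0 < 0.10


# ===========================================================================
# Bivariate von Mises (cosine model)
# ===========================================================================

class TestBvmDensity:
    def test_kappa3_zero_factorizes(self, rng):
        p = BivariateVonMisesParams(mu=1.0, nu=2.5, kappa1=8.0, kappa2=3.0, kappa3=0.0)
        p1 = VonMisesParams(mu=1.0, kappa=8.0)
        p2 = VonMisesParams(mu=2.5, kappa=3.0)
        phi = rng.uniform(0, TWO_PI, 100)
        psi = rng.uniform(0, TWO_PI, 100)
        joint = bvm_log_density(p, phi, psi)
        assert np.allclose(joint, vm_log_density(p1, phi) + vm_log_density(p2, psi),
                           atol=1e-10)

    def test_density_integrates_to_one_high_concentration(self):
        p = BivariateVonMisesParams(mu=0.3, nu=5.0, kappa1=100.0, kappa2=100.0,
                                    kappa3=49.0)
        val = torus_integral(lambda a, b: bvm_log_density(p, a, b), n=1024)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_translation_invariance(self, rng):
        delta = 0.7
        a = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=5.0, kappa2=7.0, kappa3=2.0)
        b = BivariateVonMisesParams(mu=1.0 + delta, nu=2.0, kappa1=5.0, kappa2=7.0,
                                    kappa3=2.0)
        phi = rng.uniform(0, TWO_PI, 50)
        psi = rng.uniform(0, TWO_PI, 50)
        assert np.allclose(bvm_log_density(a, phi, psi),
                           bvm_log_density(b, phi + delta, psi), atol=1e-10)


class TestBvmNormalizer:
    def test_independence_closed_form(self):
        from scipy.special import i0
        got = bvm_log_normalizer(10.0, 4.0, 0.0)
        assert got == pytest.approx(np.log(4 * np.pi ** 2 * i0(10.0) * i0(4.0)),
                                    abs=1e-10)

    def test_uniform_torus_limit(self):
        assert bvm_log_normalizer(1e-12, 1e-12, 0.0) == pytest.approx(
            np.log(4 * np.pi ** 2), abs=1e-9)

    @pytest.mark.parametrize("k1,k2,k3", [(10, 10, 5), (10, 10, -5), (3, 7, 1.5)])
    def test_series_matches_quadrature(self, k1, k2, k3):
        s = bvm_log_normalizer(k1, k2, k3, method="series")
        q = bvm_log_normalizer(k1, k2, k3, method="quadrature")
        assert abs(s - q) / abs(q) < 1e-6


class TestBvmConditionalAndSampling:
    def test_conditional_reduces_when_independent(self):
        p = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=6.0, kappa2=3.0, kappa3=0.0)
        for psi in [0.0, 1.0, 4.0]:
            c = bvm_conditional(p, psi)
            assert c.mu == pytest.approx(1.0)
            assert c.kappa == pytest.approx(6.0)

    def test_conditional_at_psi_equal_nu(self):
        p = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=6.0, kappa2=3.0, kappa3=2.0)
        c = bvm_conditional(p, 2.0)
        assert c.kappa == pytest.approx(4.0)  # kappa1 - kappa3
        assert c.mu == pytest.approx(1.0)

    def test_conditional_times_marginal_reproduces_joint(self, rng):
        p = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=10.0, kappa2=4.0, kappa3=3.0)
        # normalize the analytic psi marginal by 1D quadrature
        grid = np.linspace(0, TWO_PI, 8192, endpoint=False)
        log_marg_grid = _bvm_psi_marginal_log(p, grid)
        log_z = np.log(np.exp(log_marg_grid - log_marg_grid.max()).mean() * TWO_PI) \
            + log_marg_grid.max()
        for _ in range(50):
            phi, psi = rng.uniform(0, TWO_PI, 2)
            cond = bvm_conditional(p, psi)
            log_marg = float(_bvm_psi_marginal_log(p, np.array([psi]))[0]) - log_z
            assert bvm_log_density(p, phi, psi) == pytest.approx(
                vm_log_density(cond, phi) + log_marg, abs=1e-8)

    def test_sampling_recovers_concentration(self):
        rng = np.random.default_rng(17)
        p = BivariateVonMisesParams(mu=1.0, nu=4.0, kappa1=100.0, kappa2=100.0,
                                    kappa3=0.0)
        s = bvm_sample(p, 10_000, rng)
        est = vm_estimate(s[:, 0])
        assert abs(est.kappa - 100.0) / 100.0 < 0.10

    def test_positive_kappa3_induces_negative_circular_correlation(self):
        rng = np.random.default_rng(18)
        p = BivariateVonMisesParams(mu=1.0, nu=4.0, kappa1=100.0, kappa2=100.0,
                                    kappa3=49.0)
        s = bvm_sample(p, 10_000, rng)
        r = _circular_correlation(s[:, 0], s[:, 1])
        assert r < -0.1

    def test_circular_means_recovered(self):
        rng = np.random.default_rng(19)
        p = BivariateVonMisesParams(mu=1.0, nu=4.0, kappa1=10.0, kappa2=10.0,
                                    kappa3=0.0)
        s = bvm_sample(p, 10_000, rng)
        assert abs(_circ_mean(s[:, 0]) - 1.0) < np.deg2rad(3)
        assert abs(_circ_mean(s[:, 1]) - 4.0) < np.deg2rad(3)

    def test_independence_when_kappa3_zero(self):
        rng = np.random.default_rng(20)
        p = BivariateVonMisesParams(mu=0.5, nu=2.0, kappa1=20.0, kappa2=20.0,
                                    kappa3=0.0)
        s = bvm_sample(p, 10_000, rng)
        assert abs(_circular_correlation(s[:, 0], s[:, 1])) < 0.03


class TestBvmEstimate:
    def test_recovery_at_high_concentration_with_interaction(self):
        rng = np.random.default_rng(23)
        p = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=100.0, kappa2=100.0,
                                    kappa3=49.0)
        est = bvm_estimate(bvm_sample(p, 10_000, rng))
        assert 35.0 <= est.kappa3 <= 63.0
        assert abs(est.kappa1 - 100.0) / 100.0 < 0.15

    def test_independent_data_yields_small_kappa3(self):
        rng = np.random.default_rng(24)
        phi = vm_sample(VonMisesParams(mu=1.0, kappa=10.0), 10_000, rng)
        psi = vm_sample(VonMisesParams(mu=2.0, kappa=10.0), 10_000, rng)
        est = bvm_estimate(np.column_stack([phi, psi]))
        assert abs(est.kappa3) < 2.0

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(25)
        p = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=20.0, kappa2=30.0,
                                    kappa3=8.0)
        s = bvm_sample(p, 8_000, rng)
        delta = 0.9
        a = bvm_estimate(s)
        b = bvm_estimate(np.mod(s + delta, TWO_PI))
        assert abs(np.angle(np.exp(1j * (b.mu - a.mu - delta)))) < 1e-6
        assert abs(np.angle(np.exp(1j * (b.nu - a.nu - delta)))) < 1e-6
        assert b.kappa1 == pytest.approx(a.kappa1, rel=1e-4)
        assert b.kappa3 == pytest.approx(a.kappa3, rel=1e-3, abs=1e-3)


def _circ_mean(a):
    return np.mod(np.angle(np.exp(1j * a).mean()), TWO_PI)


def _circular_correlation(a, b):
    sa = np.sin(a - _circ_mean(a))
    sb = np.sin(b - _circ_mean(b))
    return float((sa * sb).mean() / np.sqrt((sa ** 2).mean() * (sb ** 2).mean()))


# ===========================================================================
# Kent / FB5
# ===========================================================================

class TestKentDensity:
    def test_beta_zero_reduces_to_vmf(self, rng):
        g = _frame(3)
        p = KentParams(kappa=25.0, beta=0.0, gammas=g)
        x = _rand_units(100, rng)
        assert np.allclose(kent_log_density(p, x),
                           vmf_log_density(25.0, g[0], x), atol=1e-8)

    def test_density_integrates_to_one(self):
        p = KentParams(kappa=200.0, beta=50.0, gammas=_frame())
        val = sphere_integral(lambda x: kent_log_density(p, x))
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_mode_is_mean_direction(self):
        g = _frame(7)
        p = KentParams(kappa=200.0, beta=50.0, gammas=g)
        rng = np.random.default_rng(0)
        x = np.concatenate([_rand_units(200_000, rng), g[0][None]])
        best = x[np.argmax(kent_log_density(p, x))]
        assert best @ g[0] > 0.9999

    def test_axis_sign_ambiguity(self, rng):
        g = _frame(5)
        flipped = g.copy()
        flipped[1] = -flipped[1]
        flipped[2] = -flipped[2]
        a = KentParams(kappa=50.0, beta=10.0, gammas=g)
        b = KentParams(kappa=50.0, beta=10.0, gammas=flipped)
        x = _rand_units(50, rng)
        assert np.allclose(kent_log_density(a, x), kent_log_density(b, x), atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            KentParams(kappa=10.0, beta=5.0, gammas=_frame())  # 2b = k
        bad = _frame()
        bad[1] = bad[0]
        with pytest.raises(ParameterError):
            KentParams(kappa=10.0, beta=1.0, gammas=bad)


class TestKentNormalizer:
    def test_beta_zero_closed_form(self):
        k = 100.0
        vmf = np.log(4 * np.pi) + k + np.log1p(-np.exp(-2 * k)) - np.log(2) - np.log(k)
        assert abs(kent_log_normalizer(k, 0.0, "series") - vmf) / vmf < 1e-6
        assert abs(kent_log_normalizer(k, 0.0, "approx") - vmf) / vmf < 1e-6

    def test_series_matches_monte_carlo(self):
        rng = np.random.default_rng(2)
        mc = mc_sphere_log_normalizer(10.0, 4.0, _frame(), 1_000_000, rng)
        series = kent_log_normalizer(10.0, 4.0, "series")
        assert abs(series - mc) / abs(mc) < 0.005

    def test_monotone_in_kappa(self):
        vals = [kent_log_normalizer(k, 0.0, "series") for k in [1, 5, 20, 100]]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("kappa,beta", [(50, 10), (100, 30), (500, 100)])
    def test_approx_agrees_with_series_at_high_concentration(self, kappa, beta):
        s = kent_log_normalizer(kappa, beta, "series")
        a = kent_log_normalizer(kappa, beta, "approx")
        assert abs(a - s) / abs(s) < 0.01

    def test_constraint_violation_rejected(self):
        with pytest.raises(ParameterError):
            kent_log_normalizer(10.0, 5.0)


class TestKentSampling:
    def test_high_concentration_high_ellipticity_recovery(self):
        rng = np.random.default_rng(31)
        p = KentParams(kappa=1000.0, beta=499.0, gammas=_frame())
        est = kent_estimate(kent_sample(p, 5000, rng))
        assert abs(est.kappa - 1000.0) / 1000.0 < 0.10

    def test_vmf_case_has_no_spurious_ellipticity(self):
        rng = np.random.default_rng(32)
        p = KentParams(kappa=10.0, beta=0.0, gammas=_frame())
        est = kent_estimate(kent_sample(p, 5000, rng))
        assert est.beta < 1.5

    def test_resultant_length_approaches_one(self):
        # E[rbar] = coth(kappa) - 1/kappa = 1 - 1/kappa at large kappa, so the
        # observed resultant concentrates at 0.9990 for kappa = 1000 and at
        # 0.9995 for kappa = 2000
        rng = np.random.default_rng(33)
        for kappa, floor in [(1000.0, 0.9985), (2000.0, 0.999)]:
            p = KentParams(kappa=kappa, beta=0.0, gammas=_frame())
            x = kent_sample(p, 5000, rng)
            assert np.linalg.norm(x.mean(axis=0)) > floor


class TestKentEstimate:
    def test_recovery_at_medium_concentration(self):
        rng = np.random.default_rng(34)
        p = KentParams(kappa=200.0, beta=50.0, gammas=_frame(11))
        est = kent_estimate(kent_sample(p, 5000, rng))
        assert 180.0 <= est.kappa <= 220.0
        assert abs(est.gamma1 @ p.gamma1) > np.cos(np.deg2rad(2))

    def test_symmetric_great_circle_cluster_recovers_mean(self):
        # points placed symmetrically about gamma1 along a great circle
        g = _frame()
        angs = np.deg2rad(np.array([-20, -10, -5, 5, 10, 20]))
        x = np.cos(angs)[:, None] * g[0] + np.sin(angs)[:, None] * g[1]
        est = kent_estimate(x)
        assert abs(est.gamma1 @ g[0]) > 0.999

    def test_vmf_data_gives_small_ellipticity_ratio(self):
        rng = np.random.default_rng(35)
        p = KentParams(kappa=100.0, beta=0.0, gammas=_frame(13))
        est = kent_estimate(kent_sample(p, 5000, rng))
        assert est.beta / est.kappa < 0.05

    def test_degenerate_data_rejected(self):
        with pytest.raises(EstimationError):
            kent_estimate(np.tile([0.0, 0.0, 1.0], (5, 1)))
        # antipodal pairs: vanishing resultant
        x = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 1.0, 0], [0, -1.0, 0]])
        with pytest.raises(EstimationError):
            kent_estimate(x)


# ===========================================================================
# Cross-family invariants
# ===========================================================================

KENT_GRID = [(k, f * k / 2) for k in (1.0, 10.0, 100.0, 1000.0)
             for f in (0.0, 0.5, 0.95)]
BVM_GRID = [(k, k, f * k) for k in (1.0, 10.0, 100.0) for f in (0.0, 0.49, 0.9)]


class TestNormalizationGrid:
    @pytest.mark.parametrize("kappa,beta", KENT_GRID)
    def test_kent_density_normalized(self, kappa, beta):
        p = KentParams(kappa=kappa, beta=beta, gammas=_frame())
        n_t = 4000 if kappa >= 500 else 2000
        val = sphere_integral(lambda x: kent_log_density(p, x), n_t=n_t)
        assert val == pytest.approx(1.0, abs=2e-4)

    @pytest.mark.parametrize("k1,k2,k3", BVM_GRID)
    def test_bvm_density_normalized(self, k1, k2, k3):
        p = BivariateVonMisesParams(mu=0.5, nu=1.5, kappa1=k1, kappa2=k2, kappa3=k3)
        val = torus_integral(lambda a, b: bvm_log_density(p, a, b), n=1024)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kappa", [1.0, 10.0, 100.0, 1000.0])
    def test_vm_density_normalized(self, kappa):
        p = VonMisesParams(mu=3.0, kappa=kappa)
        assert circle_integral(lambda t: vm_log_density(p, t)) == pytest.approx(
            1.0, abs=1e-8)


class TestRoundTripRecovery:
    """sample -> estimate round trips across all three directional families."""

    @pytest.mark.parametrize("seed", range(5))
    def test_vm_round_trip(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = VonMisesParams(mu=2.0, kappa=20.0)
        est = vm_estimate(vm_sample(p, 10_000, rng))
        assert abs(est.kappa - 20.0) / 20.0 < 0.10

    @pytest.mark.parametrize("seed", range(5))
    def test_bvm_round_trip(self, seed):
        rng = np.random.default_rng(200 + seed)
        p = BivariateVonMisesParams(mu=1.0, nu=2.0, kappa1=30.0, kappa2=20.0,
                                    kappa3=10.0)
        est = bvm_estimate(bvm_sample(p, 10_000, rng))
        for name in ("kappa1", "kappa2", "kappa3"):
            assert abs(getattr(est, name) - getattr(p, name)) \
                / abs(getattr(p, name)) < 0.15

    @pytest.mark.parametrize("seed", range(5))
    def test_kent_round_trip(self, seed):
        rng = np.random.default_rng(300 + seed)
        p = KentParams(kappa=100.0, beta=30.0, gammas=_frame(seed))
        est = kent_estimate(kent_sample(p, 5000, rng))
        assert abs(est.kappa - 100.0) / 100.0 < 0.10
        assert abs(est.beta - 30.0) / 30.0 < 0.25
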