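"""PID machinery: max-ent surrogate, Iccs redundancy, decomposition identities."""

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize

from avpid.gcmi import LN2, copula_normalise, mi_gg
from avpid.pid import (
    JointGaussModel,
    _GaussLogPdf,
    fit_joint_gauss,
    iccs_redundancy,
    interaction_information,
    local_pid_map,
    maxent_surrogate,
    pid_decompose,
    pid_from_model,
    pid_regions_to_stimulus,
)

# ---------------------------------------------------------------- oracles


def maxent_oracle(model: JointGaussModel) -> np.ndarray:
    """Numerically maximize log-det over the free A-V cross block.

    Independent of the closed-form construction: direct constrained
    optimization of the Gaussian entropy with all other blocks fixed.
    """
    sm, sa, sv = model.slices
    c = model.cov
    da, dv = c[sa, sv].shape

    def neg_logdet(p):
        cc = c.copy()
        cc[sa, sv] = p.reshape(da, dv)
        cc[sv, sa] = cc[sa, sv].T
        sign, ld = np.linalg.slogdet(cc)
        return np.inf if sign <= 0 else -ld

    res = minimize(
        neg_logdet, c[sa, sv].ravel(), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 50_000, "maxfev": 50_000},
    )
    cc = c.copy()
    cc[sa, sv] = res.x.reshape(da, dv)
    cc[sv, sa] = cc[sa, sv].T
    return cc


def quadrature_iccs_1d(cov: np.ndarray, nq: int = 60) -> float:
    """Deterministic Gauss-Hermite evaluation of the redundancy integral (1D blocks)."""
    model = JointGaussModel(cov, n_samples=10**6, dims=(1, 1, 1))
    me = maxent_surrogate(model)
    x, w = hermegauss(nq)
    wn = w / np.sqrt(2 * np.pi)
    L = np.linalg.cholesky(me.cov_tilde)
    pts = np.array(np.meshgrid(x, x, x, indexing="ij")).reshape(3, -1).T @ L.T
    wts = (wn[:, None, None] * wn[None, :, None] * wn[None, None, :]).ravel()
    c, ct = model.cov, me.cov_tilde
    lp = _GaussLogPdf
    i_ma = (lp(c[np.ix_([0, 1], [0, 1])])(pts[:, [0, 1]]) - lp(c[:1, :1])(pts[:, :1]) - lp(c[1:2, 1:2])(pts[:, 1:2])) / LN2
    i_mv = (lp(c[np.ix_([0, 2], [0, 2])])(pts[:, [0, 2]]) - lp(c[:1, :1])(pts[:, :1]) - lp(c[2:, 2:])(pts[:, 2:])) / LN2
    i_mav = (lp(ct)(pts) - lp(c[:1, :1])(pts[:, :1]) - lp(ct[1:, 1:])(pts[:, 1:])) / LN2
    cl = i_ma + i_mv - i_mav
    s = np.sign(i_ma)
    inc = (s == np.sign(i_mv)) & (s == np.sign(i_mav)) & (s == np.sign(cl))
    return float(np.sum(wts * np.where(inc, cl, 0.0)))


def random_model(rng: np.random.Generator, n: int = 400) -> JointGaussModel:
    x = rng.standard_normal((n, 6))
    m = x[:, :2]
    a = x[:, 2:4] + rng.uniform(0.2, 0.8) * m
    v = x[:, 4:6] + rng.uniform(0.2, 0.8) * m + rng.uniform(0.0, 0.5) * a
    return fit_joint_gauss(m, a, v)


# ---------------------------------------------------------------- tests


@pytest.mark.parametrize(
    "mi_a, mi_v, mi_av, expected",
    [(0.3, 0.3, 0.6, 0.0), (0.3, 0.3, 0.4, -0.2), (0.1, 0.1, 0.5, 0.3)],
)
def test_interaction_information_arithmetic(mi_a, mi_v, mi_av, expected):
    assert interaction_information(mi_a, mi_v, mi_av) == pytest.approx(expected)


class TestMaxEntSurrogate:
    def test_conditionally_independent_input_is_fixed_point(self):
        rng = np.random.default_rng(0)
        model = random_model(rng)
        me1 = maxent_surrogate(model)
        fixed = JointGaussModel(me1.cov_tilde, model.n_samples, model.dims)
        me2 = maxent_surrogate(fixed)
        assert np.allclose(me2.cov_tilde, me1.cov_tilde, atol=1e-12)
        assert me2.entropy_gain == pytest.approx(0.0, abs=1e-12)

    def test_entropy_never_decreases_and_blocks_preserved(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            model = random_model(rng)
            me = maxent_surrogate(model)
            sm, sa, sv = model.slices
            assert np.array_equal(me.cov_tilde[sm, sa], model.cov[sm, sa])
            assert np.array_equal(me.cov_tilde[sm, sv], model.cov[sm, sv])
            assert me.entropy_gain >= -1e-12
            # A-V partial covariance given M vanishes
            c = me.cov_tilde
            part = c[sa, sv] - c[sa, sm] @ np.linalg.inv(c[sm, sm]) @ c[sm, sv]
            assert np.abs(part).max() < 1e-8

    def test_closed_form_matches_numerical_optimizer(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            model = random_model(rng)
            assert np.abs(maxent_surrogate(model).cov_tilde - maxent_oracle(model)).max() < 1e-6

    def test_invariant_to_av_cross_block(self):
        rng = np.random.default_rng(3)
        model = random_model(rng)
        sm, sa, sv = model.slices
        c2 = model.cov.copy()
        c2[sa, sv] *= 0.5
        c2[sv, sa] *= 0.5
        model2 = JointGaussModel(c2, model.n_samples, model.dims)
        assert np.allclose(maxent_surrogate(model).cov_tilde, maxent_surrogate(model2).cov_tilde, atol=1e-12)


class TestIccsRedundancy:
    def test_independent_variables_give_zero(self):
        model = JointGaussModel(np.eye(6), n_samples=10_000)
        red, se = iccs_redundancy(model, n_mc=20_000, rng_seed=0)
        assert abs(red) <= 3 * max(se, 1e-12)

    def test_mc_standard_error_scales_with_sample_count(self):
        rng = np.random.default_rng(4)
        model = random_model(rng)
        reds1 = [iccs_redundancy(model, n_mc=10_000, rng_seed=s)[0] for s in range(50)]
        reds2 = [iccs_redundancy(model, n_mc=20_000, rng_seed=s + 100)[0] for s in range(50)]
        ratio = np.std(reds1) / np.std(reds2)
        assert abs(ratio - np.sqrt(2)) < 0.2 * np.sqrt(2)

    def test_small_mc_count_rejected(self):
        with pytest.raises(ValueError):
            iccs_redundancy(JointGaussModel(np.eye(6), 1000), n_mc=100)

    def test_duplicate_predictor_matches_quadrature_oracle(self):
        # noisy duplicate: V ~ A; redundancy is below I(M;A) by design of the
        # surrogate (invariance to the A-V dependence) but above half of it
        r, eps = 0.7, 1e-6
        cov = np.array([[1, r, r], [r, 1, 1 - eps], [r, 1 - eps, 1.0]])
        model = JointGaussModel(cov, n_samples=10**6, dims=(1, 1, 1))
        red, se = iccs_redundancy(model, n_mc=200_000, rng_seed=5)
        oracle = quadrature_iccs_1d(cov)
        mi_a = -0.5 * np.log2(1 - r**2)
        assert red == pytest.approx(oracle, abs=max(3 * se, 0.01))
        assert 0.5 * mi_a < red < mi_a

    def test_seeded_determinism(self):
        model = JointGaussModel(np.eye(6), n_samples=5000)
        assert iccs_redundancy(model, n_mc=10_000, rng_seed=9) == iccs_redundancy(model, n_mc=10_000, rng_seed=9)


class TestPidDecompose:
    def test_identities_hold_to_machine_precision(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal((2000, 2))
        a = 0.5 * m + rng.standard_normal((2000, 2))
        v = 0.5 * m + 0.3 * a + rng.standard_normal((2000, 2))
        res = pid_decompose(m, a, v, n_mc=20_000, rng_seed=0)
        assert abs(res.red + res.uni_a - res.mi_a) < 1e-12
        assert abs(res.red + res.uni_v - res.mi_v) < 1e-12
        assert abs(res.red + res.uni_a + res.uni_v + res.syn - res.mi_av) < 1e-12
        assert abs((res.syn - res.red) - interaction_information(res.mi_a, res.mi_v, res.mi_av)) < 1e-12

    def test_additive_mixture_is_net_synergistic(self):
        # target = sum of independent predictors: observing both pins it down
        rng = np.random.default_rng(7)
        a = rng.standard_normal(20_000)
        v = rng.standard_normal(20_000)
        m = a + v + 0.5 * rng.standard_normal(20_000)
        cm = copula_normalise(np.column_stack([m, a, v])).data
        res = pid_decompose(cm[:, :1], cm[:, 1:2], cm[:, 2:], n_mc=20_000, rng_seed=1)
        assert res.syn - res.red > 0
        # cross-check Eq-style net interaction from the MI estimator alone
        net = mi_gg(cm[:, :1], cm[:, 1:]) - mi_gg(cm[:, :1], cm[:, 1:2]) - mi_gg(cm[:, :1], cm[:, 2:])
        assert res.syn - res.red == pytest.approx(net, abs=1e-10)

    def test_maxent_invariance_of_red_and_unique(self):
        rng = np.random.default_rng(8)
        model = random_model(rng)
        sm, sa, sv = model.slices
        c2 = model.cov.copy()
        c2[sa, sv] *= 0.3
        c2[sv, sa] *= 0.3
        model2 = JointGaussModel(c2, model.n_samples, model.dims)
        r1 = pid_from_model(model, n_mc=20_000, rng_seed=3)
        r2 = pid_from_model(model2, n_mc=20_000, rng_seed=3)
        assert r1.red == r2.red  # same surrogate, same seed -> bit-identical
        assert r1.uni_a == pytest.approx(r2.uni_a, abs=1e-12)
        assert r1.syn != r2.syn  # joint MI depends on the A-V block

    def test_planted_kind_orderings(self, recovery_norm):
        g = recovery_norm.groupby("node")[["red", "uni_a", "uni_v", "syn"]].mean()
        assert g.loc["redundant"].idxmax() == "red"
        assert g.loc["unique_a"].idxmax() == "uni_a"
        assert g.loc["unique_v"].idxmax() == "uni_v"
        assert g.loc["synergistic"].idxmax() == "syn"


class TestLocalPidMap:
    def test_cells_sum_to_joint_mi(self):
        rng = np.random.default_rng(9)
        n = 5000
        m = rng.standard_normal(n)
        a = 0.8 * m + 0.6 * rng.standard_normal(n)
        v = 0.8 * m + 0.6 * rng.standard_normal(n)
        model = fit_joint_gauss(m[:, None], a[:, None], v[:, None])
        lm = local_pid_map(model, n_mc=100_000, rng_seed=0)
        from avpid.gcmi import gauss_entropy_bits

        c = model.cov
        mi = gauss_entropy_bits(c[:1, :1]) + gauss_entropy_bits(c[1:, 1:]) - gauss_entropy_bits(c)
        assert lm["mi"].sum() == pytest.approx(mi, abs=3 * lm["mi_se"])

    def test_independent_model_cells_near_zero(self):
        model = JointGaussModel(np.eye(3), n_samples=10_000, dims=(1, 1, 1))
        lm = local_pid_map(model, n_mc=50_000, rng_seed=1)
        assert np.abs(lm["mi"]).max() < 0.01
        assert np.abs(lm["coinfo"]).max() < 0.01

    def test_duplicate_predictor_opposite_sign_cells_carry_no_redundant_mass(self):
        r, eps = 0.7, 1e-6
        cov = np.array([[1, r, r], [r, 1, 1 - eps], [r, 1 - eps, 1.0]])
        model = JointGaussModel(cov, n_samples=10**6, dims=(1, 1, 1))
        lm = local_pid_map(model, n_mc=100_000, rng_seed=2)
        same_sign = np.abs(np.array([lm["iccs"][:, 0, 0], lm["iccs"][:, 1, 1]]))
        opp_sign = np.abs(np.array([lm["iccs"][:, 0, 1], lm["iccs"][:, 1, 0]]))
        # sign-consistent redundancy concentrates where A and V agree
        assert opp_sign.max() < 0.1 * same_sign.max()


class TestRegionsToStimulus:
    def test_independent_stimulus_gives_null_terms(self):
        rng = np.random.default_rng(10)
        n1 = rng.standard_normal((3000, 2))
        n2 = 0.5 * n1 + rng.standard_normal((3000, 2))
        stim = rng.standard_normal((3000, 2))
        res = pid_regions_to_stimulus(n1, n2, stim, n_mc=20_000, rng_seed=0)
        for term in (res.red, res.uni_a, res.uni_v, res.syn):
            assert abs(term) < 0.02

    def test_shared_drive_nodes_are_redundant_about_stimulus(self):
        rng = np.random.default_rng(11)
        n = 5000
        d = rng.standard_normal(n)
        stim = d + 0.4 * rng.standard_normal(n)
        n1 = d + 0.4 * rng.standard_normal(n)
        n2 = d + 0.4 * rng.standard_normal(n)
        res = pid_regions_to_stimulus(n1[:, None], n2[:, None], stim[:, None], n_mc=30_000, rng_seed=1)
        assert res.red == max(res.red, res.uni_a, res.uni_v, res.syn)

    def test_complementary_nodes_are_synergistic_about_stimulus(self):
        rng = np.random.default_rng(12)
        n = 5000
        d1 = rng.standard_normal(n)
        d2 = rng.standard_normal(n)
        stim = d1 + d2 + 0.4 * rng.standard_normal(n)
        comp = pid_regions_to_stimulus(d1[:, None], d2[:, None], stim[:, None], n_mc=30_000, rng_seed=2)
        # matched-power control: both nodes carry the same mixture
        ctrl1 = (d1 + d2 + 0.4 * rng.standard_normal(n)) / np.sqrt(2)
        ctrl2 = (d1 + d2 + 0.4 * rng.standard_normal(n)) / np.sqrt(2)
        ctrl = pid_regions_to_stimulus(ctrl1[:, None], ctrl2[:, None], stim[:, None], n_mc=30_000, rng_seed=3)
        assert comp.syn > ctrl.syn
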