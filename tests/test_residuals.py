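import numpy as np
import pytest
from scipy import stats

from petconn.residuals import (
    edge_extremeness,
    fit_control_model,
    group_residual_contrast,
    residual,
    residual_network,
    split_controls,
    sum_abs_residuals,
    welch_compare,
)

from conftest import make_roi_connectome

NAMES3 = ("A", "B", "C")


def conn3(ab, ac, bc, subject_id=""):
    return make_roi_connectome(
        [[1, ab, ac], [ab, 1, bc], [ac, bc, 1]], NAMES3, subject_id=subject_id
    )


def control_set(rng, n=10, center=(0.5, 0.3, 0.7), sd=0.05):
    return [
        conn3(*(np.clip(center + sd * rng.standard_normal(3), 0.01, 0.99)))
        for _ in range(n)
    ]


class TestFitControlModel:
    def test_identical_controls(self):
        conns = [conn3(0.5, 0.3, 0.7)] * 10
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_control_model(conns)
        assert np.allclose(model.means, [0.5, 0.3, 0.7])
        assert np.all(model.bandwidths == 1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        conns = control_set(rng)
        m1 = fit_control_model(conns)
        m2 = fit_control_model(conns[::-1])
        assert np.allclose(sorted(m1.values[0]), sorted(m2.values[0]))
        assert np.allclose(m1.means, m2.means)
        assert np.allclose(m1.bandwidths, m2.bandwidths)

    def test_bimodal_mean(self):
        conns = [conn3(v, 0.5, 0.5) for v in [0.1] * 5 + [0.9] * 5]
        model = fit_control_model(conns)
        assert model.means[model.edge_id(("A", "B"))] == pytest.approx(0.5)

    def test_too_few_controls(self):
        with pytest.raises(ValueError, match="5"):
            fit_control_model([conn3(0.5, 0.5, 0.5)] * 4)

    def test_mismatched_roi_sets(self):
        bad = make_roi_connectome(np.eye(3), ("A", "B", "D"))
        with pytest.raises(ValueError, match="mismatch"):
            fit_control_model([conn3(0.5, 0.5, 0.5)] * 5 + [bad])


@pytest.mark.filterwarnings("ignore:.*degenerate")
class TestEdgeExtremeness:
    def test_symmetric_sample_center(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(0.05, 0.45, 10)
        vals = np.concatenate([u, 1.0 - u])  # exactly symmetric around 0.5
        conns = [conn3(v, 0.5, 0.5) for v in vals]
        model = fit_control_model(conns)
        assert edge_extremeness(model, ("A", "B"), 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_tail_limit(self):
        rng = np.random.default_rng(2)
        model = fit_control_model(control_set(rng))
        assert edge_extremeness(model, ("A", "B"), 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_oracle(self):
        rng = np.random.default_rng(3)
        sample = rng.standard_normal(200)
        conns = [conn3(v, 0.5, 0.5) for v in sample]
        # loosen the [0,1] convention: make_roi_connectome allows any C here
        model = fit_control_model(conns)
        eid = model.edge_id(("A", "B"))
        c = sample.mean() + 3 * sample.std()
        p = edge_extremeness(model, eid, c)
        # numeric integration of the same Gaussian KDE on a fine grid
        h = model.bandwidths[eid]
        grid = np.linspace(sample.min() - 6 * h, c, 20001)
        dens = np.mean(stats.norm.pdf((grid[:, None] - sample[None, :]) / h) / h, axis=1)
        f_hat = np.trapezoid(dens, grid)
        expected = 2 * min(f_hat, 1 - f_hat)
        assert p == pytest.approx(expected, abs=0.02)

    def test_unknown_edge(self):
        rng = np.random.default_rng(4)
        model = fit_control_model(control_set(rng))
        with pytest.raises(KeyError):
            edge_extremeness(model, ("A", "Z"), 0.5)


@pytest.mark.filterwarnings("ignore:.*degenerate")
class TestResidual:
    def test_arithmetic_identity(self):
        assert 1 - 0.01**0.25 == pytest.approx(0.6838, abs=5e-5)

    def test_formula_consistency(self):
        rng = np.random.default_rng(5)
        model = fit_control_model(control_set(rng))
        for c in (0.2, 0.5, 0.62):
            for kappa in (0.25, 1.0):
                p = edge_extremeness(model, ("A", "B"), c)
                r = residual(model, ("A", "B"), c, kappa)
                expected = np.sign(model.means[model.edge_id(("A", "B"))] - c) * (1 - p**kappa)
                assert r == pytest.approx(expected)
                assert abs(r) <= 1

    def test_kappa_domain(self):
        rng = np.random.default_rng(6)
        model = fit_control_model(control_set(rng))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="kappa"):
                residual(model, ("A", "B"), 0.5, bad)

    def test_small_kappa_emphasizes_rare(self):
        # |r| ratio rare/typical is larger at kappa=0.25 than at kappa=1
        rare, typical = 0.01, 0.5
        ratio_small = (1 - rare**0.25) / (1 - typical**0.25)
        ratio_one = (1 - rare) / (1 - typical)
        assert ratio_small > ratio_one


class TestResidualNetwork:
    def test_central_subject_near_zero(self):
        rng = np.random.default_rng(7)
        conns = control_set(rng, n=20)
        model = fit_control_model(conns)
        center = conn3(*model.means)
        rn = residual_network(center, model, kappa=1.0)
        assert np.all(np.abs(rn.r) < 0.05)
        assert np.allclose(np.diag(rn.r), 0.0)
        assert np.allclose(rn.r, rn.r.T)

    def test_kappa_monotonicity(self):
        # |r| = 1 - p^kappa grows with kappa for p in (0, 1); small kappa
        # shrinks every |r| but shrinks the non-extreme ones the most,
        # which is the relative emphasis tested in TestResidual
        rng = np.random.default_rng(8)
        model = fit_control_model(control_set(rng, n=20))
        subject = conn3(0.62, 0.18, 0.81)
        r_small = residual_network(subject, model, 0.25).r
        r_big = residual_network(subject, model, 0.75).r
        assert np.all(np.abs(r_big) + 1e-12 >= np.abs(r_small))

    def test_roi_mismatch_error(self):
        rng = np.random.default_rng(9)
        model = fit_control_model(control_set(rng))
        other = make_roi_connectome(np.eye(3), ("A", "B", "D"))
        with pytest.raises(ValueError, match="D"):
            residual_network(other, model, 0.5)

    def test_effect_raises_sum_abs_residuals(self, reference_cohort):
        _, conns, groups = reference_cohort
        controls = [c for c, g in zip(conns, groups) if g == "control"]
        patients = [c for c, g in zip(conns, groups) if g == "patient"]
        model = fit_control_model(controls)
        s_pat = [sum_abs_residuals(residual_network(c, model, 0.25)) for c in patients]
        s_ctl = [sum_abs_residuals(residual_network(c, model, 0.25)) for c in controls]
        assert np.median(s_pat) > np.median(s_ctl)
        assert min(s_pat) > np.percentile(s_ctl, 75)


class TestSumAbsResiduals:
    def test_zero(self):
        from petconn.residuals import ResidualNetwork

        rn = ResidualNetwork(NAMES3, np.zeros((3, 3)), kappa=1.0)
        assert sum_abs_residuals(rn) == 0.0

    def test_78_edges(self):
        from petconn.residuals import ResidualNetwork

        n = 13
        r = np.full((n, n), 0.5)
        np.fill_diagonal(r, 0.0)
        rn = ResidualNetwork(tuple(f"R{i}" for i in range(n)), r, kappa=1.0)
        assert sum_abs_residuals(rn) == pytest.approx(0.5 * 78)

    def test_double_loop_oracle(self):
        from petconn.residuals import ResidualNetwork

        rng = np.random.default_rng(10)
        m = rng.uniform(-1, 1, (5, 5))
        r = (m + m.T) / 2
        np.fill_diagonal(r, 0.0)
        rn = ResidualNetwork(tuple("ABCDE"), r, kappa=1.0)
        brute = sum(
            abs(r[i, j]) for i in range(5) for j in range(i + 1, 5)
        )
        assert sum_abs_residuals(rn) == pytest.approx(brute)


class TestSplitControls:
    def test_paper_scale_sizes(self):
        controls = list(range(46))
        fit, other = split_controls(controls, n_holdout=10, seed=0)
        assert len(fit) == 36 and len(other) == 10

    def test_seeded_and_partition(self):
        controls = list(range(20))
        a = split_controls(controls, 7, seed=3)
        b = split_controls(controls, 7, seed=3)
        assert a == b
        fit, other = a
        assert sorted(fit + other) == controls
        assert not set(fit) & set(other)

    def test_too_large_holdout(self):
        with pytest.raises(ValueError):
            split_controls(list(range(5)), 5, seed=0)


class TestWelch:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        t, p = welch_compare(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_computation(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        t, p = welch_compare(a, b)
        # independent closed-form Welch t and Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        assert t == pytest.approx(t_exp)
        assert p == pytest.approx(p_exp)

    def test_type_one_calibration(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            welch_compare(rng.standard_normal(20), rng.standard_normal(20))[1] < 0.05
            for _ in range(200)
        )
        assert 0.02 <= rejections / 200 <= 0.09

    def test_degenerate_variance(self):
        assert welch_compare([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = welch_compare([2.0, 2.0], [1.0, 1.0])
        assert p == 0.0 and t > 0


class TestGroupResidualContrast:
    def _rn(self, r):
        from petconn.residuals import ResidualNetwork

        return ResidualNetwork(NAMES3, np.asarray(r, float), kappa=1.0)

    def test_identical_groups_zero(self):
        rns = [self._rn([[0, 0.5, -0.2], [0.5, 0, 0.1], [-0.2, 0.1, 0]])] * 3
        assert np.allclose(group_residual_contrast(rns, rns), 0.0)

    def test_injected_edge_is_argmax(self):
        base = np.zeros((3, 3))
        eff = base.copy()
        eff[0, 1] = eff[1, 0] = 0.8
        a = [self._rn(eff)] * 4
        b = [self._rn(base)] * 4
        out = group_residual_contrast(a, b)
        assert np.unravel_index(np.argmax(out), out.shape) in [(0, 1), (1, 0)]

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(12)

        def rand_rn():
            m = rng.uniform(-1, 1, (3, 3))
            r = (m + m.T) / 2
            np.fill_diagonal(r, 0.0)
            return self._rn(r)

        a = [rand_rn() for _ in range(4)]
        b = [rand_rn() for _ in range(4)]
        assert np.allclose(
            group_residual_contrast(a, b), group_residual_contrast(a[::-1], b[::-1])
        )
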