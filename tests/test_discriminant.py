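import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import cross_val_score

from rmda.datamodel import DesignSet, ResponsePanel
from rmda.discriminant import (
    DiscriminantRule,
    RepeatedMeasuresClassifier,
    build_rule,
    classify_individual,
    linear_score,
    matrix_from_panel,
    panel_from_matrix,
    pool_covariance,
    quadratic_score,
    resub_accuracy,
)
from rmda.simgen import SimCondition, gen_normal


class TestPoolCovariance:
    def test_equal_inputs_unchanged(self, rng):
        A = rng.normal(size=(3, 3))
        O = A @ A.T + np.eye(3)
        assert np.allclose(pool_covariance(O, O, 10, 20), O)

    def test_equal_sizes_simple_average(self):
        assert np.allclose(pool_covariance(np.eye(2), 3 * np.eye(2), 8, 8),
                           2 * np.eye(2))

    def test_unequal_group_arithmetic(self):
        # (31 * I + 47 * 3I) / 78
        O = pool_covariance(np.eye(4), 3 * np.eye(4), 32, 48)
        assert np.allclose(O, (172 / 78) * np.eye(4))

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            pool_covariance(np.eye(2), np.eye(2), 1, 1)


class TestScores:
    def test_midpoint_equal_priors_on_boundary(self, rng):
        mu1, mu2 = rng.normal(size=3), rng.normal(size=3)
        y = 0.5 * (mu1 + mu2)
        assert abs(linear_score(y, mu1, mu2, np.eye(3), 0.5, 0.5)) < 1e-12

    def test_identical_means_score_is_prior_term(self, rng):
        mu = rng.normal(size=3)
        s = linear_score(rng.normal(size=3), mu, mu, np.eye(3), 0.25, 0.75)
        assert np.isclose(s, -np.log(3.0))

    def test_scalar_linear_example(self):
        # mu1=1, mu2=-1, Omega=1, y=2: (2 - 0) * 2 = 4 > 0 -> group 1
        assert np.isclose(linear_score([2.0], [1.0], [-1.0], [[1.0]], 0.5, 0.5), 4.0)

    def test_quadratic_equals_twice_linear_when_equal_cov(self, rng):
        mu1, mu2 = rng.normal(size=4), rng.normal(size=4)
        A = rng.normal(size=(4, 4))
        O = A @ A.T + 4 * np.eye(4)
        for _ in range(5):
            y = rng.normal(size=4)
            ls = linear_score(y, mu1, mu2, O, 0.4, 0.6)
            qs = quadratic_score(y, mu1, mu2, O, O, 0.4, 0.6)
            assert np.isclose(qs, 2 * ls)

    def test_quadratic_at_group1_mean_nonnegative(self, rng):
        mu1, mu2 = rng.normal(size=3), rng.normal(size=3)
        O = 2.0 * np.eye(3)  # |O1| = |O2|, equal priors
        s = quadratic_score(mu1, mu1, mu2, O, O, 0.5, 0.5)
        assert s >= 0

    def test_scalar_quadratic_variance_only(self):
        # equal means, Omega1=1, Omega2=3, y at the common mean:
        # score = -log(1/3) = log 3 -> group 1 (the tighter-variance group
        # is penalized away from the point? no: smaller |Omega1| favored)
        s = quadratic_score([0.0], [0.0], [0.0], [[1.0]], [[3.0]], 0.5, 0.5)
        assert np.isclose(s, np.log(3.0))


class _FixedFit:
    """Stub group model with constant mean/covariance for rule tests."""

    def __init__(self, mu, Omega):
        self.mu = np.asarray(mu, dtype=float)
        self.Omega = np.asarray(Omega, dtype=float)

    def fitted_means(self, design):
        return np.tile(self.mu, (design.n_individuals, 1))

    def omega_factors(self, design):
        mu = self.fitted_means(design)
        s = np.sqrt(np.diag(self.Omega))
        C = self.Omega / np.outer(s, s)
        return mu, np.broadcast_to(s, mu.shape), C


def _toy_panel(values, labels=None):
    v = np.asarray(values, dtype=float)[:, None, :]
    panel = ResponsePanel(v, ["gaussian"],
                          group_label=None if labels is None else np.asarray(labels))
    design = DesignSet(x=np.zeros(v.shape[0]), t=np.arange(1.0, v.shape[2] + 1))
    return panel, design


class TestClassification:
    def test_tie_goes_to_group_two(self):
        f = _FixedFit([0.0, 0.0], np.eye(2))
        rule = DiscriminantRule("linear", f, f, 0.5, 0.5, 5, 5)
        panel, design = _toy_panel([[1.0, -1.0]])
        assert classify_individual(rule, panel, design, 0) == 2

    def test_equal_means_larger_prior_wins(self, rng):
        f = _FixedFit([0.0, 0.0], np.eye(2))
        rule = DiscriminantRule("linear", f, f, 0.3, 0.7, 3, 7)
        panel, design = _toy_panel(rng.normal(size=(10, 2)))
        assert np.all(rule.predict(panel, design) == 2)

    def test_relabeling_flips_decisions(self, rng):
        f1 = _FixedFit([1.0, 2.0], np.eye(2))
        f2 = _FixedFit([-1.0, 0.5], 2 * np.eye(2))
        panel, design = _toy_panel(rng.normal(size=(20, 2)))
        for kind in ("linear", "quadratic"):
            r12 = DiscriminantRule(kind, f1, f2, 0.4, 0.6, 4, 6)
            r21 = DiscriminantRule(kind, f2, f1, 0.6, 0.4, 6, 4)
            p12 = r12.predict(panel, design)
            p21 = r21.predict(panel, design)
            # swapping group identities flips every (non-tied) assignment
            assert np.all((p12 == 1) == (p21 == 2))

    def test_well_separated_individual(self):
        f1 = _FixedFit([5.0, 5.0], np.eye(2))
        f2 = _FixedFit([-5.0, -5.0], np.eye(2))
        rule = DiscriminantRule("quadratic", f1, f2, 0.5, 0.5, 5, 5)
        panel, design = _toy_panel([[5.2, 4.9]])
        assert classify_individual(rule, panel, design, 0) == 1


class TestResubAccuracy:
    def test_all_correct(self):
        f1 = _FixedFit([4.0], [[1.0]])
        f2 = _FixedFit([-4.0], [[1.0]])
        rule = DiscriminantRule("linear", f1, f2, 0.5, 0.5, 2, 2)
        panel, design = _toy_panel([[4.1], [3.9], [-4.2], [-3.8]],
                                   labels=[1, 1, 2, 2])
        acc, per = resub_accuracy(rule, panel, design)
        assert acc == 1.0 and per[1] == 1.0 and per[2] == 1.0

    def test_three_of_four(self):
        f1 = _FixedFit([4.0], [[1.0]])
        f2 = _FixedFit([-4.0], [[1.0]])
        rule = DiscriminantRule("linear", f1, f2, 0.5, 0.5, 2, 2)
        panel, design = _toy_panel([[4.1], [-3.9], [-4.2], [-3.8]],
                                   labels=[1, 1, 2, 2])
        acc, per = resub_accuracy(rule, panel, design)
        assert acc == 0.75 and per[1] == 0.5 and per[2] == 1.0

    def test_empty_panel_rejected(self):
        f = _FixedFit([0.0], [[1.0]])
        rule = DiscriminantRule("linear", f, f, 0.5, 0.5, 1, 1)
        with pytest.raises(ValueError):
            panel, design = _toy_panel(np.zeros((0, 1)))
            resub_accuracy(rule, panel, design)

    def test_chance_level_against_uninformative_rule(self, rng):
        f = _FixedFit([0.0, 0.0], np.eye(2))
        # equal priors, identical means: scores are exactly 0 -> all group 2
        rule = DiscriminantRule("linear", f, f, 0.5, 0.5, 50, 50)
        labels = rng.permutation(np.repeat([1, 2], 500))
        panel, design = _toy_panel(rng.normal(size=(1000, 2)), labels=labels)
        acc, _ = resub_accuracy(rule, panel, design)
        assert abs(acc - 0.5) < 0.05


class TestAffineInvariance:
    def test_scores_invariant_under_common_linear_map(self, rng):
        d = 4
        mu1, mu2 = rng.normal(size=d), rng.normal(size=d)
        A = rng.normal(size=(d, d))
        O1 = A @ A.T + d * np.eye(d)
        O2 = 0.5 * O1 + np.eye(d)
        T = rng.normal(size=(d, d)) + 2 * np.eye(d)  # invertible w.h.p.
        for _ in range(3):
            y = rng.normal(size=d)
            ls = linear_score(y, mu1, mu2, O1, 0.4, 0.6)
            lsT = linear_score(T @ y, T @ mu1, T @ mu2, T @ O1 @ T.T, 0.4, 0.6)
            assert np.isclose(ls, lsT, rtol=1e-8)
            qs = quadratic_score(y, mu1, mu2, O1, O2, 0.4, 0.6)
            qsT = quadratic_score(T @ y, T @ mu1, T @ mu2, T @ O1 @ T.T,
                                  T @ O2 @ T.T, 0.4, 0.6)
            # the log-det terms shift by the same 2 log|T| in both groups
            assert np.isclose(qs, qsT, rtol=1e-8)


class TestBayesLimit:
    def test_one_dimensional_error_rate_converges(self, rng):
        # two unit-variance gaussians a distance Delta apart: the plug-in
        # linear rule's error rate approaches Phi(-Delta/2)
        delta = 1.5
        n = 4000
        y1 = rng.normal(delta / 2, 1.0, size=n)
        y2 = rng.normal(-delta / 2, 1.0, size=n)
        mu1h, mu2h = y1.mean(), y2.mean()
        s2h = 0.5 * (y1.var(ddof=1) + y2.var(ddof=1))
        f1 = _FixedFit([mu1h], [[s2h]])
        f2 = _FixedFit([mu2h], [[s2h]])
        rule = DiscriminantRule("linear", f1, f2, 0.5, 0.5, n, n)
        panel, design = _toy_panel(np.concatenate([y1, y2])[:, None],
                                   labels=np.repeat([1, 2], n))
        acc, _ = resub_accuracy(rule, panel, design)
        bayes_err = stats.norm.cdf(-delta / 2)
        assert abs((1 - acc) - bayes_err) < 0.02


class TestBuildRule:
    def test_gee_and_mle_rules_fit_and_score(self):
        cond = SimCondition("normal", 3, 3, 120, 60, 60, "ar1", 0.3, 1.0)
        panel, design = gen_normal(cond, 21)
        for est in ("gee", "mle"):
            for kind in ("linear", "quadratic"):
                r = build_rule(panel, design, estimator=est, rule=kind)
                acc, per = resub_accuracy(r, panel, design)
                assert 0.4 <= acc <= 1.0
                assert set(per) == {1, 2}

    def test_mle_quadratic_reduces_to_linear(self):
        # the covariance-pattern comparator shares one covariance, so its
        # quadratic rule must reproduce its linear rule's decisions
        cond = SimCondition("normal", 3, 3, 100, 40, 60, "ar1", 0.7, 3.0)
        panel, design = gen_normal(cond, 22)
        rl = build_rule(panel, design, estimator="mle", rule="linear")
        rq = build_rule(panel, design, estimator="mle", rule="quadratic")
        assert np.array_equal(rl.predict(panel, design),
                              rq.predict(panel, design))


class TestSklearnFrontEnd:
    @pytest.fixture
    def Xy(self):
        cond = SimCondition("normal", 3, 3, 150, 75, 75, "ar1", 0.3, 1.0)
        panel, design = gen_normal(cond, 23)
        X = matrix_from_panel(panel, design)
        return X, panel.group_label

    def test_fit_predict_shapes(self, Xy):
        X, y = Xy
        clf = RepeatedMeasuresClassifier(n_responses=3, n_occasions=3).fit(X, y)
        pred = clf.predict(X)
        assert pred.shape == y.shape
        assert set(np.unique(pred)) <= {1, 2}
        assert clf.n_features_in_ == 10

    def test_clone_and_params_roundtrip(self):
        clf = RepeatedMeasuresClassifier(n_responses=3, n_occasions=5,
                                         estimator="mle", rule="quadratic")
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    def test_cross_val_score_runs(self, Xy):
        X, y = Xy
        clf = RepeatedMeasuresClassifier(n_responses=3, n_occasions=3)
        scores = cross_val_score(clf, X, y, cv=3)
        assert scores.shape == (3,) and np.all(scores > 0.3)

    def test_matrix_panel_roundtrip(self, Xy):
        X, y = Xy
        panel, design = panel_from_matrix(X, 3, 3, ["gaussian"] * 3,
                                          [1.0, 2.0, 3.0], y=y)
        assert np.allclose(matrix_from_panel(panel, design), X)
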