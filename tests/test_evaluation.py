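import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faceutil.evaluation import (
    ErrorReport,
    OrdinalLogisticFamily,
    compare_models,
    compute_mze_mae,
    fit_ordinal_logistic,
    loocv_evaluate,
)
from faceutil.evaluation.ologit import _label_probs, predict_ologit
from faceutil.gpor import OrdinalDataset


class TestComputeMzeMae:
    def test_perfect_prediction(self):
        assert compute_mze_mae([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_arithmetic_example(self):
        mze, mae = compute_mze_mae([1, 2, 3], [2, 2, 5])
        assert mze == pytest.approx(2 / 3)
        assert mae == pytest.approx(1.0)

    def test_uniform_random_predictor_chance_level(self, rng):
        # chance MZE over a 5-point scale is 1 - 1/5 = 0.8
        n = 100_000
        truth = rng.integers(1, 6, size=n)
        pred = rng.integers(1, 6, size=n)
        mze, _ = compute_mze_mae(pred, truth)
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(mze - 0.8) < 3 * se

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_mze_mae([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(1, 50),
        seed=st.integers(0, 10_000),
        r=st.integers(2, 7),
    )
    def test_bounds(self, n, seed, r):
        rng = np.random.default_rng(seed)
        pred = rng.integers(1, r + 1, size=n)
        truth = rng.integers(1, r + 1, size=n)
        mze, mae = compute_mze_mae(pred, truth)
        assert 0.0 <= mze <= 1.0
        assert 0.0 <= mae <= r - 1


class TestFitOrdinalLogistic:
    def test_intercept_only_matches_empirical_frequencies(self):
        y = np.array([1] * 3 + [2] * 5 + [3] * 2)
        data = OrdinalDataset(x=np.zeros((10, 0)), y=y, r=3)
        model = fit_ordinal_logistic(data)
        from scipy.special import expit

        cum = expit(model.cutpoints)
        np.testing.assert_allclose(cum, [0.3, 0.8], atol=1e-4)

    def test_tiny_dataset_matches_grid_search(self):
        # brute-force oracle: 0.01-step grid over (beta, c1, c2)
        x = np.array([[-1.0], [-0.6], [-0.2], [0.2], [0.6], [1.0]])
        y = np.array([1, 1, 2, 2, 3, 3])
        data = OrdinalDataset(x=x, y=y, r=3)
        model = fit_ordinal_logistic(data)

        from scipy.special import expit

        # 0.01-step grids for beta and c1; the bound only weakens if c2 is
        # coarser, so 0.05 there keeps the oracle honest and fast
        c1_grid = np.arange(-3, 3, 0.01)
        c2_grid = np.arange(-3, 3, 0.05)
        ordered = c2_grid[:, None] > c1_grid[None, :]  # [c2, c1]
        best = -np.inf
        for beta in np.arange(-6, 6, 0.01):
            lin = x[:, 0] * beta
            e1 = expit(c1_grid[:, None] - lin[None, :])  # (n_c1, 6)
            e2 = expit(c2_grid[:, None] - lin[None, :])  # (n_c2, 6)
            # labels are y = (1,1,2,2,3,3): P1 from c1, P3 from c2, P2 couples
            lp1 = np.log(e1[:, 0] * e1[:, 1])
            lp3 = np.log((1 - e2[:, 4]) * (1 - e2[:, 5]))
            p2 = (e2[:, None, 2] - e1[None, :, 2]) * (e2[:, None, 3] - e1[None, :, 3])
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = lp1[None, :] + lp3[:, None] + np.log(p2)  # [c2, c1]
            m = np.max(np.where(ordered, ll, -np.inf))
            if m > best:
                best = m
        assert model.loglik >= best - 0.01

    def test_label_reversal_symmetry(self, rng):
        x = rng.normal(size=(50, 2))
        lin = x @ [0.8, -0.5]
        y = np.digitize(lin + rng.logistic(size=50), [-0.5, 0.5]) + 1
        data = OrdinalDataset(x=x, y=y, r=3)
        rev = OrdinalDataset(x=x, y=4 - y, r=3)
        m1 = fit_ordinal_logistic(data)
        m2 = fit_ordinal_logistic(rev)
        np.testing.assert_allclose(m2.beta, -m1.beta, atol=1e-4)
        np.testing.assert_allclose(m2.cutpoints, -m1.cutpoints[::-1], atol=1e-4)
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-6)

    def test_complete_separation_flagged(self):
        x = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([1, 1, 1, 2, 2, 2])
        model = fit_ordinal_logistic(OrdinalDataset(x=x, y=y, r=2))
        assert not model.converged
        assert np.isfinite(model.loglik)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            fit_ordinal_logistic(
                OrdinalDataset(x=rng.normal(size=(5, 1)), y=[2] * 5, r=3)
            )
        with pytest.raises(ValueError):
            fit_ordinal_logistic(
                OrdinalDataset(x=rng.normal(size=(2, 2)), y=[1, 2], r=3)
            )

    def test_matches_statsmodels(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        x = rng.normal(size=(80, 2))
        lin = x @ [1.0, -0.7]
        y = np.digitize(lin + rng.logistic(size=80), [-1, 0, 1]) + 1
        data = OrdinalDataset(x=x, y=y, r=4)
        ours = fit_ordinal_logistic(data)
        theirs = OrderedModel(y - 1, x, distr="logit").fit(method="bfgs", disp=0)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-4)


class _ModeFamily:
    """Predicts the modal training label everywhere (ties -> smaller label)."""

    def fit(self, data):
        counts = np.bincount(data.y, minlength=data.r + 1)
        return int(np.argmax(counts[1:]) + 1)

    def predict(self, fitted, x):
        return np.full(np.atleast_2d(x).shape[0], fitted)


class TestLoocvEvaluate:
    def test_perfectly_predictable_data(self, rng):
        # wide class margin: every fold's decision boundary stays in the gap
        x = np.concatenate([np.linspace(-2, -1, 10), np.linspace(1, 2, 10)])[:, None]
        y = (x[:, 0] > 0).astype(int) + 1
        data = OrdinalDataset(x=x, y=y, r=2)
        _, rep = loocv_evaluate(data, OrdinalLogisticFamily())
        assert rep.mze_test == 0.0

    def test_n2_opposite_labels_both_wrong(self):
        # symmetric mode predictor on two opposite labels: each fold predicts
        # the other point's label
        data = OrdinalDataset(x=[[-1.0], [1.0]], y=[1, 2], r=2)
        preds, rep = loocv_evaluate(data, _ModeFamily())
        assert rep.mze_test == 1.0
        np.testing.assert_array_equal(preds, [2, 1])

    def test_mode_family_hand_enumeration(self):
        # counts (3,1,1,1,1): removing one of the '1' labels leaves mode 1;
        # removing a non-1 label leaves mode 1 as well -> predictions all 1
        y = np.array([1, 1, 1, 2, 3, 4, 5])
        data = OrdinalDataset(x=np.zeros((7, 1)), y=y, r=5)
        preds, rep = loocv_evaluate(data, _ModeFamily())
        np.testing.assert_array_equal(preds, np.ones(7))
        assert rep.mze_test == pytest.approx(4 / 7)
        assert rep.mae_test == pytest.approx((0 + 0 + 0 + 1 + 2 + 3 + 4) / 7)

    def test_order_invariance(self, rng):
        x = rng.normal(size=(15, 1))
        y = rng.integers(1, 4, size=15)
        data = OrdinalDataset(x=x, y=y, r=3)
        perm = rng.permutation(15)
        shuffled = OrdinalDataset(x=x[perm], y=y[perm], r=3)
        _, rep_a = loocv_evaluate(data, _ModeFamily())
        _, rep_b = loocv_evaluate(shuffled, _ModeFamily())
        assert rep_a.mze_test == rep_b.mze_test
        assert rep_a.mae_test == rep_b.mae_test

    def test_fold_failures_recorded_not_silent(self, rng):
        class FlakyFamily(_ModeFamily):
            calls = 0

            def fit(self, data):
                FlakyFamily.calls += 1
                if FlakyFamily.calls == 2:
                    raise RuntimeError("synthetic failure")
                return super().fit(data)

        data = OrdinalDataset(x=np.zeros((5, 1)), y=[1, 1, 2, 2, 2], r=2)
        with pytest.warns(UserWarning, match="fold"):
            _, rep = loocv_evaluate(data, FlakyFamily())
        assert rep.n_failed_folds == 1

    def test_too_few_trials(self):
        data = OrdinalDataset(x=[[0.0]], y=[1], r=2)
        with pytest.raises(ValueError):
            loocv_evaluate(data, _ModeFamily())


class TestErrorReportValidation:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ErrorReport(mze_test=1.2, mze_train=0.0, mae_test=0.0, mae_train=0.0)
        with pytest.raises(ValueError):
            ErrorReport(mze_test=0.5, mze_train=0.0, mae_test=-0.1, mae_train=0.0)


class TestCompareModels:
    def test_identical_reports(self):
        cmp = compare_models([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert cmp.t == 0.0
        assert cmp.cohen_d == 0.0
        assert not cmp.degenerate

    def test_constant_difference_degenerate(self):
        cmp = compare_models([0.6, 0.7, 0.8], [0.5, 0.6, 0.7])
        assert np.isinf(cmp.t) and cmp.t > 0
        assert cmp.degenerate

    def test_five_participant_hand_computation(self):
        a = np.array([0.70, 0.65, 0.80, 0.55, 0.60])
        b = np.array([0.60, 0.70, 0.65, 0.50, 0.45])
        diff = a - b
        sd = diff.std(ddof=1)
        t_hand = diff.mean() / (sd / np.sqrt(5))
        d_hand = diff.mean() / sd
        cmp = compare_models(a, b)
        assert cmp.t == pytest.approx(t_hand, abs=1e-12)
        assert cmp.cohen_d == pytest.approx(d_hand, abs=1e-12)
        assert cmp.df == 4
        from scipy import stats

        assert cmp.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_hand), 4), abs=1e-12
        )

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            compare_models([0.5], [0.4])


def test_predict_ologit_probs_sum_to_one(rng):
    x = rng.normal(size=(30, 1))
    y = np.digitize(x[:, 0] + rng.logistic(size=30), [-0.5, 0.5]) + 1
    model = fit_ordinal_logistic(OrdinalDataset(x=x, y=y, r=3))
    probs, y_hat = predict_ologit(model, rng.normal(size=(10, 1)))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((y_hat >= 1) & (y_hat <= 3))


def test_label_probs_monotone_cumulative(rng):
    probs = _label_probs(rng.normal(size=(5, 2)), np.array([1.0, -0.5]),
                         np.array([-1.0, 0.0, 1.0]))
    assert probs.shape == (5, 4)
    assert np.all(probs > 0)
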