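import numpy as np
import pytest
from scipy import stats

from faceutil.design import SessionConfig
from faceutil.morphometrics import (
    asymmetric_component,
    fit_face_space,
    gpa_align,
    symmetrize,
)
from faceutil.synthetic_data import (
    ParticipantSpec,
    SimulatedParticipant,
    TrueUtility,
    default_symmetry_map,
    evaluate_true_utility,
    generate_shape_population,
    label_distribution,
    make_participant,
    simulate_response,
    simulate_study,
    template_face,
)


class TestShapePopulation:
    def test_template_is_symmetric(self):
        sym = default_symmetry_map(80)
        tpl = template_face(80)
        assert np.abs(asymmetric_component(tpl, sym)).max() < 1e-9

    def test_noise_free_single_factor_is_rank_one(self):
        configs = generate_shape_population(
            40, 12, [1.0], noise_sd=0.0, seed=0, transform_jitter=False
        )
        space = fit_face_space(configs, n_pcs=1)
        assert space.explained_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_planted_ratios_recovered_through_pipeline(self):
        # factors with variances 4:2:1, tiny iso noise, full GPA+symmetrize+PCA
        sds = [2.0, np.sqrt(2.0), 1.0]
        sym = default_symmetry_map(20)
        configs = generate_shape_population(
            500, 20, sds, noise_sd=0.01, symmetry_map=sym, seed=11
        )
        res = gpa_align(configs)
        symmetrized = [symmetrize(c, sym) for c in res.aligned]
        space = fit_face_space(symmetrized, n_pcs=3)
        planted = np.array([4.0, 2.0, 1.0]) / 7.0
        np.testing.assert_allclose(space.explained_ratio, planted, atol=0.03)

    def test_seed_reproducibility(self):
        a = generate_shape_population(10, 8, [1.0, 0.5], noise_sd=0.1, seed=4)
        b = generate_shape_population(10, 8, [1.0, 0.5], noise_sd=0.1, seed=4)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.points, cb.points)

    def test_inconsistent_symmetry_map_rejected(self):
        sym = default_symmetry_map(10)
        with pytest.raises(ValueError):
            generate_shape_population(20, 12, [1.0], symmetry_map=sym, seed=0)

    def test_increasing_factor_sds_rejected(self):
        with pytest.raises(ValueError):
            generate_shape_population(20, 8, [1.0, 2.0], seed=0)


class TestTrueUtility:
    def test_quadratic_peak_value_and_symmetry(self):
        u = TrueUtility(
            kind="quadratic_peak",
            params={"peak": np.array([0.5, -0.5]), "curvature": 0.3},
            amplitude=2.0,
        )
        assert evaluate_true_utility(u, np.array([0.5, -0.5])) == pytest.approx(2.0)
        delta = np.array([0.3, -0.7])
        peak = np.array([0.5, -0.5])
        assert evaluate_true_utility(u, peak + delta) == pytest.approx(
            evaluate_true_utility(u, peak - delta)
        )

    def test_bimodal_peak_heights(self):
        u = TrueUtility(
            kind="bimodal",
            params={
                "peak1": [-1.5, 0.0], "peak2": [1.5, 0.0],
                "height1": 2.0, "height2": 1.2, "width": 0.4,
            },
        )
        # direct formula check: cross-talk between bumps 3.75 widths apart is
        # below 2e-3, and the pointwise max removes it entirely at the peaks
        assert evaluate_true_utility(u, np.array([-1.5, 0.0])) == pytest.approx(2.0)
        assert evaluate_true_utility(u, np.array([1.5, 0.0])) == pytest.approx(1.2)

    def test_gp_sample_deterministic_and_finite(self):
        u = TrueUtility(
            kind="gp_sample",
            params={"n_dims": 3, "lengthscale": 1.0, "seed": 5},
            amplitude=1.5,
        )
        x = np.random.default_rng(0).uniform(-2, 2, size=(50, 3))
        a = evaluate_true_utility(u, x)
        b = evaluate_true_utility(u, x)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            TrueUtility(kind="cubic")


def _participant(seed=0, noise_sd=1.0, peak=(0.0, 0.0)):
    u = TrueUtility(
        kind="quadratic_peak", params={"peak": np.asarray(peak), "curvature": 0.3},
        amplitude=2.0,
    )
    return SimulatedParticipant(
        utility=u, thresholds=np.array([-1.5, -0.5, 0.5, 1.5]), noise_sd=noise_sd,
        seed=seed,
    )


class TestSimulateResponse:
    def test_noise_free_low_utility_always_label_one(self):
        p = _participant(noise_sd=1e-9, peak=(2.0, 2.0))
        x = np.array([-2.0, -2.0])  # utility far below b_1
        assert all(simulate_response(p, x) == 1 for _ in range(20))

    def test_frequencies_match_analytic_distribution(self):
        p = _participant(seed=42)
        x = np.array([0.5, 0.5])
        n = 100_000
        draws = np.array([simulate_response(p, x) for _ in range(n)])
        freq = np.bincount(draws, minlength=6)[1:] / n
        probs = label_distribution(p, x)
        se = np.sqrt(probs * (1 - probs) / n)
        np.testing.assert_array_less(np.abs(freq - probs), 3 * se + 1e-12)
        # chi-square goodness of fit at alpha = 0.001
        chi2 = n * np.sum((freq - probs) ** 2 / probs)
        assert chi2 < stats.chi2.ppf(0.999, df=4)

    def test_seeded_stream_reproducible(self):
        xs = np.random.default_rng(1).uniform(-2, 2, size=(30, 2))
        a = [_participant(seed=9)(x) for x in xs]
        b = [_participant(seed=9)(x) for x in xs]
        assert a == b

    def test_reset_rewinds_stream(self):
        p = _participant(seed=3)
        xs = np.random.default_rng(2).uniform(-2, 2, size=(10, 2))
        first = [p(x) for x in xs]
        p.reset()
        second = [p(x) for x in xs]
        assert first == second


class TestSimulateStudy:
    def test_single_participant_random_design(self):
        cfg = SessionConfig(
            n_practice=0, n_random=45, n_adaptive=0, n_dims=3, refit_hyper="never"
        )
        result = simulate_study(1, session_config=cfg, seed=0)
        assert len(result.datasets) == 1
        assert result.datasets[0].n == 45
        assert result.true_peaks.shape == (1, 3)

    def test_bit_identical_for_same_seed(self):
        cfg = SessionConfig(
            n_practice=2, n_random=8, n_adaptive=2, n_dims=2, refit_hyper="never"
        )
        spec = ParticipantSpec(shared_peak=(0.5, -0.5))
        a = simulate_study(2, session_config=cfg, participant_spec=spec, seed=5)
        b = simulate_study(2, session_config=cfg, participant_spec=spec, seed=5)
        for da, db in zip(a.datasets, b.datasets):
            np.testing.assert_array_equal(da.x, db.x)
            np.testing.assert_array_equal(da.y, db.y)
        np.testing.assert_array_equal(a.true_peaks, b.true_peaks)

    def test_seed_extension_preserves_existing_participants(self):
        cfg = SessionConfig(
            n_practice=0, n_random=6, n_adaptive=0, n_dims=2, refit_hyper="never"
        )
        spec = ParticipantSpec(shared_peak=(0.0, 0.0))
        small = simulate_study(2, session_config=cfg, participant_spec=spec, seed=3)
        large = simulate_study(4, session_config=cfg, participant_spec=spec, seed=3)
        for da, db in zip(small.datasets, large.datasets[:2]):
            np.testing.assert_array_equal(da.x, db.x)
            np.testing.assert_array_equal(da.y, db.y)

    def test_default_study_scale(self):
        # structural check only: defaults encode 40 raters x 60 test trials
        cfg = SessionConfig()
        assert cfg.n_random + cfg.n_adaptive == 60
        assert cfg.n_practice == 20
        assert cfg.r == 5

    def test_participant_peaks_jitter_around_shared(self):
        spec = ParticipantSpec(shared_peak=(0.5, -0.5, 0.5), peak_jitter_sd=0.3)
        peaks = np.array(
            [make_participant(spec, seed)[1] for seed in range(200)]
        )
        np.testing.assert_allclose(
            peaks.mean(axis=0), [0.5, -0.5, 0.5], atol=3 * 0.3 / np.sqrt(200)
        )
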