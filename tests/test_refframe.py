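import numpy as np
import pytest
from scipy import stats

from gravframe import (
    ExperimentGeometry,
    PopulationSpec,
    SimNeuronConfig,
    classify_neuron,
    counterroll_sweep,
    pearson_r,
    perm_test_positive,
    population_com_test,
    simulate_neuron,
    simulate_population,
    summarize_population,
)
from gravframe.refframe import NeuronFrameResult, analyze_neurons, iter_condition_tunings
from gravframe.tuning import ComparisonSet, TuningFunction, boxcar_matrix, comparison_weight_matrices, mean_tuning


def make_cs(a, b):
    a = np.asarray(a, float)
    return ComparisonSet(frame="gravitational", orientations=np.arange(a.size) * 12.5,
                         values_a=a, values_b=np.asarray(b, float))


class TestPearson:
    def test_identical_and_reversed_vectors(self):
        v = [1.0, 4.0, 9.0, 16.0, 25.0]
        assert pearson_r(make_cs(v, v)) == pytest.approx(1.0)
        assert pearson_r(make_cs(v, v[::-1])) == pytest.approx(
            stats.pearsonr(v, v[::-1]).statistic
        )

    def test_toy_pairs_match_covariance_formula(self):
        a = np.array([1, 2, 3, 4, 5], float)
        b = np.array([2, 1, 4, 3, 6], float)
        # direct product-moment formula as the oracle
        expected = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert pearson_r(make_cs(a, b)) == pytest.approx(expected)
        assert pearson_r(make_cs(a, b)) == pytest.approx(stats.pearsonr(a, b).statistic)

    def test_zero_variance_is_undefined_not_a_number(self):
        assert pearson_r(make_cs([3, 3, 3, 3], [1, 2, 3, 4])) is None


def naive_perm_test(tfa, tfb, geom, frame, n_perm, rng, width=3):
    """Independent oracle: explicit loop, per-draw smoothing and readout."""
    smooth = boxcar_matrix(len(geom.grid), width)
    _, wa, wb = comparison_weight_matrices(geom, frame)
    obs = np.corrcoef(wa @ smooth @ tfa.values, wb @ smooth @ tfb.values)[0, 1]
    hits = 0
    for _ in range(n_perm):
        va = rng.permutation(tfa.values)
        vb = rng.permutation(tfb.values)
        r = np.corrcoef(wa @ smooth @ va, wb @ smooth @ vb)[0, 1]
        hits += r >= obs - 1e-12
    return obs, (1 + hits) / (1 + n_perm)


class TestPermTest:
    def test_matched_sharp_tuning_is_highly_significant(self, body_geom):
        cfg = SimNeuronConfig(theta_pref=15.0, kappa=8.0, noise_model="gaussian",
                              sigma=1.0, frame_weight_lambda=1.0)
        trials = simulate_neuron(cfg, body_geom, np.random.default_rng(0))
        tfa = mean_tuning(trials, 0, 1)
        tfb = mean_tuning(trials, 0, 2)
        r, p = perm_test_positive(tfa, tfb, body_geom, "gravitational",
                                  n_perm=10_000, rng=np.random.default_rng(1))
        assert r > 0.95 and p <= 0.001

    def test_agrees_with_naive_loop_oracle(self, body_geom):
        rng = np.random.default_rng(2)
        for frame in ("gravitational", "retinal"):
            vals_a = rng.normal(10, 3, 9)
            vals_b = vals_a + rng.normal(0, 2, 9)
            tfa = TuningFunction(0, 1, "screen", body_geom.grid, vals_a)
            tfb = TuningFunction(0, 2, "screen", body_geom.grid, vals_b)
            r_fast, p_fast = perm_test_positive(
                tfa, tfb, body_geom, frame, n_perm=4000, rng=np.random.default_rng(3)
            )
            r_slow, p_slow = naive_perm_test(
                tfa, tfb, body_geom, frame, 4000, np.random.default_rng(4)
            )
            assert r_fast == pytest.approx(r_slow)
            se = np.sqrt(p_slow * (1 - p_slow) / 4000)
            assert abs(p_fast - p_slow) < 4 * se + 2 / 4000

    def test_zero_permutations_degenerates_to_p_one(self, body_geom):
        rng = np.random.default_rng(5)
        tfa = TuningFunction(0, 1, "screen", body_geom.grid, rng.normal(size=9))
        tfb = TuningFunction(0, 2, "screen", body_geom.grid, rng.normal(size=9))
        _, p = perm_test_positive(tfa, tfb, body_geom, "gravitational", n_perm=0)
        assert p == 1.0

    def test_flat_curve_is_excluded(self, body_geom):
        tfa = TuningFunction(0, 1, "screen", body_geom.grid, np.full(9, 5.0))
        tfb = TuningFunction(0, 2, "screen", body_geom.grid, np.arange(9.0))
        r, p = perm_test_positive(tfa, tfb, body_geom, "gravitational", n_perm=100,
                                  rng=np.random.default_rng(0))
        assert r is None and p is None

    def test_type_one_error_calibrated_at_alpha(self, body_geom):
        # untuned neurons: the two conditions' curves are independent noise
        spec = PopulationSpec(
            n_neurons=250,
            proportions={"untuned": 1.0, "gravitational": 0, "retinal": 0, "mixed": 0},
            noise_model="gaussian", sigma_range=(4.0, 4.0),
        )
        trials, _ = simulate_population(spec, body_geom, np.random.default_rng(6))
        res = analyze_neurons(trials, body_geom, n_perm=500, rng=np.random.default_rng(7))
        for ps in ([r.p_grav for r in res], [r.p_ret for r in res]):
            rate = np.mean(np.asarray(ps) < 0.05)
            half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(ps))
            assert abs(rate - 0.05) < half_width + 1e-12


class TestClassifyAndSummarize:
    @pytest.mark.parametrize(
        "p_grav, p_ret, expected",
        [
            (0.01, 0.30, "gravitational"),
            (0.30, 0.01, "retinal"),
            (0.04, 0.04, "both"),
            (0.5, 0.5, "neither"),
            (0.05, 0.2, "neither"),  # boundary: p == alpha is not significant
            (None, 0.01, "excluded"),
        ],
    )
    def test_label_truth_table(self, p_grav, p_ret, expected):
        assert classify_neuron(p_grav, p_ret) == expected

    def test_proportions_among_significant(self):
        labels = ["gravitational"] * 33 + ["retinal"] * 11 + ["both"] * 8 + ["neither"] * 37
        results = [
            NeuronFrameResult(i, 0.5, 0.5, 0.01, 0.01, lab) for i, lab in enumerate(labels)
        ]
        s = summarize_population(results)
        assert s.n_total == 89 and s.n_significant == 52
        assert s.proportions["gravitational"] == pytest.approx(33 / 52)
        assert s.proportions["retinal"] == pytest.approx(11 / 52)
        assert s.proportions["both"] == pytest.approx(8 / 52)
        assert sum(s.counts.values()) == s.n_total

    def test_all_neither_flags_undefined_proportions(self):
        results = [NeuronFrameResult(0, 0.1, 0.1, 0.5, 0.5, "neither")]
        s = summarize_population(results)
        assert s.n_significant == 0 and s.proportions is None


class TestPopulationComTest:
    def test_gravity_population_reaches_floor_on_gravitational_axis(self, body_geom):
        spec = PopulationSpec(
            n_neurons=30,
            proportions={"gravitational": 1.0, "retinal": 0, "mixed": 0, "untuned": 0},
            noise_model="gaussian", sigma_range=(0.5, 0.5),
        )
        trials, _ = simulate_population(spec, body_geom, np.random.default_rng(8))
        pairs = [(a, b) for _, a, b in iter_condition_tunings(trials, body_geom)]
        n_perm = 2000
        com, p = population_com_test(pairs, body_geom, "gravitational",
                                     n_perm=n_perm, rng=np.random.default_rng(9))
        assert com > 0.95
        assert p <= 1.01 / (n_perm + 1)

    def test_preshuffled_values_give_null_p(self, body_geom):
        # destroy the cross-condition pairing; p should be unremarkable
        rng = np.random.default_rng(10)
        pairs = []
        for _ in range(40):
            pairs.append(
                (
                    TuningFunction(0, 1, "screen", body_geom.grid, rng.normal(10, 3, 9)),
                    TuningFunction(0, 2, "screen", body_geom.grid, rng.normal(10, 3, 9)),
                )
            )
        _, p = population_com_test(pairs, body_geom, "gravitational",
                                   n_perm=1000, rng=np.random.default_rng(11))
        assert p > 0.05


class TestCounterrollSweep:
    def _retina_trials(self, geom, counterroll, seed=12, n=40):
        gen_geom = ExperimentGeometry(counterroll_deg=counterroll)
        spec = PopulationSpec(
            n_neurons=n,
            proportions={"retinal": 1.0, "gravitational": 0, "mixed": 0, "untuned": 0},
            noise_model="gaussian", amplitude_range=(40.0, 40.0), sigma_range=(4.0, 4.0),
        )
        trials, _ = simulate_population(spec, gen_geom, np.random.default_rng(seed))
        return trials

    @pytest.mark.parametrize("true_cr", [6.0, 0.0])
    def test_argmax_recovers_generative_counterroll(self, body_geom, true_cr):
        trials = self._retina_trials(body_geom, true_cr)
        sweep = counterroll_sweep(trials, body_geom, candidate_angles=range(13))
        assert sweep.informative
        assert abs(sweep.argmax_deg - true_cr) <= 1.0

    def test_candidates_must_include_zero(self, body_geom):
        trials = self._retina_trials(body_geom, 6.0)
        with pytest.raises(ValueError, match="include 0"):
            counterroll_sweep(trials, body_geom, candidate_angles=[2.0, 4.0, 6.0])

    def test_gravity_only_selection_flagged_uninformative(self, body_geom):
        # gravity-anchored neurons: retinal correspondence keeps rising with
        # compensation, so no interior maximum exists to localize
        spec = PopulationSpec(
            n_neurons=30,
            proportions={"gravitational": 1.0, "retinal": 0, "mixed": 0, "untuned": 0},
            noise_model="gaussian", amplitude_range=(40.0, 40.0), sigma_range=(4.0, 4.0),
        )
        trials, _ = simulate_population(spec, body_geom, np.random.default_rng(13))
        sweep = counterroll_sweep(trials, body_geom, candidate_angles=range(13))
        assert not sweep.informative and sweep.argmax_deg is None

    def test_overcompensating_candidates_marked_invalid(self, body_geom):
        trials = self._retina_trials(body_geom, 6.0, n=10)
        sweep = counterroll_sweep(trials, body_geom, candidate_angles=[0, 6, 30])
        assert np.isnan(sweep.mean_correlation[-1])
        assert sweep.argmax_deg != 30.0
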