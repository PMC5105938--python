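"""Time-to-onset distribution: oracle equivalence, calibration, risk."""

import numpy as np
import pytest

from osaprog.errors import OsaprogError
from osaprog.prognosis import (OnsetDistribution, evaluate_predictions,
                               path_enumeration_pmf, predict_from_state,
                               risk_indicator, time_to_onset_distribution)
from osaprog.state_graph import APNEIC, NON_APNEIC, BlockGraph, BlockQuantizer
from osaprog.synthetic_data import (first_passage_samples,
                                    generate_markov_fixture)


class TestGeometricClosedForm:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_pmf_and_expectation(self, p):
        g = generate_markov_fixture(2, 1, self_loop=1.0 - p)
        d = time_to_onset_distribution(g, 0, horizon=400)
        t = np.arange(1, 401)
        np.testing.assert_allclose(d.pmf, (1 - p) ** (t - 1) * p, atol=1e-12)
        assert d.expectation == pytest.approx(1.0 / p, rel=1e-6)

    def test_risk_indicator_geometric(self):
        g = generate_markov_fixture(2, 1, self_loop=0.7)
        d = time_to_onset_distribution(g, 0, horizon=100)
        assert risk_indicator(d, 2) == pytest.approx(1 - 0.7 ** 2)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_matrix_power_equals_path_enumeration(self, seed):
        g = generate_markov_fixture(5, 2, seed=seed)
        pe = path_enumeration_pmf(g, 0, 4)
        mp = time_to_onset_distribution(g, 0, horizon=4).pmf
        np.testing.assert_allclose(mp, pe, atol=1e-12)

    def test_matches_monte_carlo_histogram(self):
        g = generate_markov_fixture(5, 2, seed=7)
        d = time_to_onset_distribution(g, 0, horizon=10)
        n = 20_000
        hits = first_passage_samples(g, 0, n, seed=2)
        for t in range(1, 6):
            p = d.pmf[t - 1]
            freq = np.mean(hits == t)
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(freq - p) <= 3 * se + 1e-9


class TestDistributionInvariants:
    def test_conservation(self):
        g = generate_markov_fixture(4, 1, seed=5)
        d = time_to_onset_distribution(g, 0, horizon=30)
        assert d.pmf.sum() + d.mass_beyond_horizon == pytest.approx(1.0, abs=1e-12)
        assert d.risk(30) == pytest.approx(1.0 - d.mass_beyond_horizon)

    @pytest.mark.parametrize("seed", range(10))
    def test_risk_non_decreasing(self, seed):
        g = generate_markov_fixture(6, 2, seed=seed)
        d = time_to_onset_distribution(g, 0, horizon=40)
        risks = [d.risk(t) for t in range(1, 41)]
        assert np.all(np.diff(risks) >= -1e-12)

    def test_higher_entry_probability_shortens_expectation(self):
        g = generate_markov_fixture(5, 2, seed=9)
        d1 = time_to_onset_distribution(g, 0, horizon=200)
        # move 30% of each transient row's transient mass to an apneic block
        P2 = g.P.copy()
        for i in g.transient_indices:
            shift = 0.3 * P2[i, g.transient_indices].sum()
            P2[i, g.transient_indices] *= 0.7
            P2[i, g.n_blocks - 1] += shift
        g2 = BlockGraph(g.block_ids, g.labels, P2)
        d2 = time_to_onset_distribution(g2, 0, horizon=200)
        assert d2.expectation <= d1.expectation

    def test_apneic_start_is_degenerate(self):
        g = generate_markov_fixture(3, 1, seed=1)
        d = time_to_onset_distribution(g, 2, horizon=10)
        assert d.onset_now
        assert d.expectation == 0.0
        assert d.risk(5) == 1.0

    def test_unreachable_apneic_set_flagged(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        g = BlockGraph([(0,), (1,)], [NON_APNEIC, APNEIC], P)
        with pytest.warns(UserWarning):
            d = time_to_onset_distribution(g, 0, horizon=20)
        assert d.mass_beyond_horizon == pytest.approx(1.0)
        assert np.isinf(d.expectation)

    def test_ci_brackets_expectation(self):
        g = generate_markov_fixture(6, 2, seed=4)
        d = time_to_onset_distribution(g, 0, horizon=200)
        assert d.ci_low <= d.expectation <= d.ci_high

    def test_out_of_range_risk_rejected(self):
        g = generate_markov_fixture(2, 1, self_loop=0.5)
        d = time_to_onset_distribution(g, 0, horizon=10)
        with pytest.raises(OsaprogError):
            d.risk(11)


class TestPredictFromState:
    @staticmethod
    def _graph_with_quantizer():
        states = np.array([[0.1], [0.2], [0.9], [0.95], [0.15], [0.92]])
        from osaprog.state_graph import quantize
        block_ids, assignment, q = quantize(states, bins_per_dim=2)
        P = np.array([[0.7, 0.3], [0.0, 1.0]])
        centroids = np.vstack([states[assignment == b].mean(0)
                               for b in range(len(block_ids))])
        return BlockGraph(block_ids, [NON_APNEIC, APNEIC], P,
                          centroids=centroids, quantizer=q)

    def test_visited_cell_composes_with_block_distribution(self):
        g = self._graph_with_quantizer()
        d1 = predict_from_state(np.array([0.12]), g, horizon=20)
        d2 = time_to_onset_distribution(g, 0, horizon=20)
        np.testing.assert_allclose(d1.pmf, d2.pmf)

    def test_apneic_cell_flagged_onset_now(self):
        g = self._graph_with_quantizer()
        assert predict_from_state(np.array([0.93]), g, horizon=20).onset_now

    def test_equidistant_tie_goes_to_smaller_block(self):
        states = np.array([[0.0], [1.0]])
        from osaprog.state_graph import quantize
        block_ids, _, q = quantize(states, bins_per_dim=2)
        g = BlockGraph(block_ids, [NON_APNEIC, APNEIC],
                       np.array([[0.5, 0.5], [0.0, 1.0]]),
                       centroids=states.astype(float),
                       quantizer=BlockQuantizer([10.0], [11.0], 2))
        # 0.5 is equidistant from both centroids; quantizer never fires
        d = predict_from_state(np.array([0.5]), g, horizon=10)
        assert d.start_block == 0


class TestEvaluation:
    @staticmethod
    def _point_mass(value, horizon=60):
        pmf = np.zeros(horizon)
        pmf[value - 1] = 1.0
        return OnsetDistribution(pmf, 0, horizon)

    def test_exact_predictions_have_r2_one(self):
        obs = np.arange(2.0, 14.0)
        preds = [self._point_mass(int(o)) for o in obs]
        rep = evaluate_predictions(preds, obs)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.coverage == 1.0

    def test_known_noise_gives_predicted_r2(self):
        """R² ≈ signal variance / total variance when noise s.d. is known."""
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            true = rng.integers(2, 30, size=200).astype(float)
            noise = rng.normal(0, 3.0, size=200)
            preds = [self._point_mass(int(t)) for t in true]
            rep = evaluate_predictions(preds, true + noise)
            r2s.append(rep.r2)
        var_sig = np.var(np.arange(2, 30))
        expected = 1.0 - 9.0 / (var_sig + 9.0)
        assert abs(np.mean(r2s) - expected) < 0.05

    def test_degenerate_observed_variance(self):
        preds = [self._point_mass(5)] * 12
        with pytest.warns(UserWarning):
            rep = evaluate_predictions(preds, np.full(12, 5.0))
        assert np.isnan(rep.r2)

    def test_calibrated_chain_covers_95(self):
        """Data generated from the fitted chain itself: CI coverage ≈ 95%."""
        g = generate_markov_fixture(6, 2, seed=21)
        start = 0
        d = time_to_onset_distribution(g, start, horizon=300)
        obs = first_passage_samples(g, start, 500, seed=5).astype(float)
        rep = evaluate_predictions([d] * 500, obs)
        assert 0.90 <= rep.coverage <= 0.99
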