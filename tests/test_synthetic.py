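"""Ground-truth generators: state covariances, Markov chains, cohorts."""

import numpy as np
import pytest

import dfncstates as d
from dfncstates.synthetic import (
    default_group_transitions,
    default_network_blocks,
    temporal_feature_families,
)
from dfncstates.windows import pair_index


class TestStateCovariances:
    def test_zero_coupling_gives_identity(self):
        covs = d.make_state_covariances(4, 1, block_spec=[{"within": 0.0, "between": 0.0}])
        np.testing.assert_allclose(covs[0].matrix, np.eye(4), atol=1e-12)

    def test_default_53x3_valid_and_distinct(self):
        covs = d.make_state_covariances(53, 3)
        assert len(covs) == 3
        rows, cols = pair_index(53)
        for sc in covs:
            assert sc.matrix.shape == (53, 53)
            np.testing.assert_allclose(np.diag(sc.matrix), 1.0)
            assert np.linalg.eigvalsh(sc.matrix).min() > 0
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(covs[i].matrix[rows, cols], covs[j].matrix[rows, cols])[0, 1]
                assert r < 0.9

    def test_affine_related_block_patterns_rejected_as_indistinguishable(self):
        # two states that are affine transforms of the same within-block
        # indicator correlate at exactly 1 in pattern space: correlation
        # distance cannot separate them, and the generator must say so
        specs = [
            {"within": 0.8, "between": -0.3},
            {"within": 0.2, "between": 0.0},
        ]
        blocks = {"A": np.arange(3), "B": np.arange(3, 6)}
        with pytest.raises(ValueError, match="not distinguishable"):
            d.make_state_covariances(6, 2, block_spec=specs, blocks=blocks)

    def test_structurally_contrasting_specs_decorrelated(self):
        # states differing in which block pair couples are separable patterns
        specs = [
            {"within": 0.6, "between": 0.0, "pairs": {("A", "B"): 0.5}},
            {"within": 0.6, "between": 0.0, "pairs": {("B", "C"): 0.5, ("A", "B"): -0.3}},
        ]
        blocks = {"A": np.arange(2), "B": np.arange(2, 4), "C": np.arange(4, 6)}
        covs = d.make_state_covariances(6, 2, block_spec=specs, blocks=blocks)
        rows, cols = pair_index(6)
        r = np.corrcoef(covs[0].matrix[rows, cols], covs[1].matrix[rows, cols])[0, 1]
        assert r < 0.5

    def test_unrepairable_template_names_state(self):
        # strong uniform negative coupling among many components cannot be PD
        bad = [{"within": -0.9, "between": -0.9}]
        with pytest.raises(ValueError, match="state 0"):
            d.make_state_covariances(10, 1, block_spec=bad, blocks={"all": np.arange(10)})

    def test_coupling_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            d.make_state_covariances(4, 1, block_spec=[{"within": 1.0}])

    def test_block_partition_covers_components(self):
        blocks = default_network_blocks(53)
        sizes = [len(v) for v in blocks.values()]
        assert sum(sizes) == 53 and len(blocks) == 7


class TestStateSequence:
    def test_absorbing_identity_transition(self):
        seq = d.simulate_state_sequence(np.eye(3), 10, initial=1, seed=0)
        np.testing.assert_array_equal(seq, np.ones(10, dtype=int))

    def test_uniform_transition_occupancy(self):
        t = np.full((3, 3), 1.0 / 3.0)
        seq = d.simulate_state_sequence(t, 30000, seed=1)
        ocr = d.occupancy_rate(seq, 3)
        assert np.abs(ocr - 1.0 / 3.0).max() <= 0.01

    def test_self_transition_recovery_counting_oracle(self):
        t = np.full((3, 3), 0.05)
        np.fill_diagonal(t, 0.9)
        seq = d.simulate_state_sequence(t, 20000, seed=2)
        # independent counting oracle
        from_0 = np.sum(seq[:-1] == 0)
        stay_0 = np.sum((seq[:-1] == 0) & (seq[1:] == 0))
        assert abs(stay_0 / from_0 - 0.9) <= 0.02

    def test_invalid_column_reported(self):
        bad = np.array([[0.5, 0.3], [0.4, 0.7]])
        with pytest.raises(ValueError, match="column 0"):
            d.simulate_state_sequence(bad, 10, seed=0)

    def test_stationary_construction_round_trip(self):
        pi = np.array([0.2, 0.5, 0.3])
        t = d.transition_matrix_for_stationary(pi, stay=0.8)
        np.testing.assert_allclose(t.sum(axis=0), 1.0)
        np.testing.assert_allclose(d.stationary_distribution(t), pi, atol=1e-12)


class TestTimecourses:
    def test_independent_channels_uncorrelated(self):
        covs = d.make_state_covariances(2, 1, block_spec=[{"within": 0.0}], blocks={"all": np.arange(2)})
        tc, regime = d.simulate_timecourses(covs, np.zeros(500, dtype=int), obs_noise_sd=0.0, seed=0)
        r = np.corrcoef(tc.data.T)[0, 1]
        assert abs(r) < 0.05
        assert tc.data.shape == (5000, 2)
        assert regime.shape == (5000,)

    def test_single_state_correlation_recovered(self):
        covs = d.make_state_covariances(
            2, 1, block_spec=[{"within": 0.8}], blocks={"all": np.arange(2)}
        )
        tc, _ = d.simulate_timecourses(covs, np.zeros(500, dtype=int), obs_noise_sd=0.0, seed=3)
        r = np.corrcoef(tc.data.T)[0, 1]
        # sampling bound ~ 1.96 (1 - r^2) / sqrt(T)
        assert abs(r - 0.8) <= 1.96 * (1 - 0.8**2) / np.sqrt(5000) + 0.02

    def test_label_out_of_range(self):
        covs = d.make_state_covariances(3, 1, block_spec=[{"within": 0.2}], blocks={"all": np.arange(3)})
        with pytest.raises(ValueError, match="labels"):
            d.simulate_timecourses(covs, np.array([0, 1]), seed=0)

    def test_truncation(self):
        covs = d.make_state_covariances(3, 1, block_spec=[{"within": 0.2}], blocks={"all": np.arange(3)})
        tc, regime = d.simulate_timecourses(covs, np.zeros(16, dtype=int), n_timepoints=159, seed=0)
        assert tc.data.shape == (159, 3) and regime.shape == (159,)


class TestCohort:
    def test_all_healthy_scores_zero(self):
        coh = d.generate_cohort(6, 0, c=6, seed=0)
        assert (coh.metadata["cdr_sob"] == 0).all()

    def test_impaired_scores_in_band(self, small_cohort):
        impaired = small_cohort.metadata.query("group == 'impaired'")
        assert ((impaired["cdr_sob"] >= 0.5) & (impaired["cdr_sob"] <= 9.0)).all()
        healthy = small_cohort.metadata.query("group == 'healthy'")
        assert (healthy["cdr_sob"] == 0).all()

    def test_bitwise_reproducible(self):
        a = d.generate_cohort(4, 3, c=8, seed=77)
        b = d.generate_cohort(4, 3, c=8, seed=77)
        for ta, tb in zip(a.scans, b.scans):
            np.testing.assert_array_equal(ta.data, tb.data)
        assert a.metadata.equals(b.metadata)

    def test_group_transitions_have_intended_occupancy_order(self):
        trans = default_group_transitions(3)
        pi_h = d.stationary_distribution(trans["healthy"])
        pi_i = d.stationary_distribution(trans["impaired"])
        assert pi_h[2] > pi_i[2]  # healthy spend more time in the linked-high state
        assert pi_i[0] > pi_h[0]
        assert pi_h[1] == pytest.approx(pi_i[1])

    def test_null_slope_gives_null_association(self):
        trans = default_group_transitions(3)
        null_trans = {"healthy": trans["healthy"], "impaired": trans["healthy"]}
        coh = d.generate_cohort(
            60,
            40,
            include_timecourses=False,
            group_transition_matrices=null_trans,
            score_model={"slope": 0.0},
            samples_per_state_step=1,
            n_timepoints=139,
            seed=5,
        )
        fams, clin = temporal_feature_families(coh, 3)
        res = d.run_association(fams, clin)
        ocr = res.table[res.table.family == "ocr"]
        assert not ocr.significant.any()

    def test_feature_level_cohort_shapes(self):
        coh = d.generate_cohort(
            10, 5, include_timecourses=False, samples_per_state_step=1, n_timepoints=139, seed=6
        )
        fams, clin = temporal_feature_families(coh, 3)
        assert fams["hmm"].shape == (15, 9) and fams["ocr"].shape == (15, 3)
        assert len(coh.scans) == 0
        assert all(s.true_state_sequence.shape == (139,) for s in coh.subjects)


class TestClassificationCohort:
    def test_row_counts(self):
        X, y = d.generate_classification_cohort(85, 40, seed=0)
        assert X.shape[0] == 125
        assert int(np.sum(y == 0)) == 85 and int(np.sum(y == 1)) == 40

    def test_effect_size_controls_separability(self):
        X, y = d.generate_classification_cohort(85, 40, n_features=10, effect_size=3.0, seed=1)
        report = d.evaluate_conversion(X, y, n_repeats=3, seed=0)
        assert report.mean_auc > 0.9

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            d.generate_classification_cohort(5, 10)
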