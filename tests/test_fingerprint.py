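"""Fingerprinting mechanics on controlled toy inputs.

These tests exercise the ranking / greedy-selection / similarity /
threshold / matching machinery on small synthetic label sequences whose
identity structure is planted directly, independent of the signal
pipeline (the end-to-end behaviour is covered by the acceptance suite).
"""

import numpy as np
import pytest

from docm.fingerprint import (differentiability, edge_logliks,
                              external_match, fit_edge_models,
                              identification_accuracy, learn_thresholds,
                              pd_feature_matrix, rank_edges,
                              similarity_matrix, stepwise_select,
                              subnetwork_performance)


def make_identity_cohort(n_subjects=4, n_edges=6, informative=(0, 1, 2),
                         T=400, seed=0):
    """Label sequences where only ``informative`` edges carry identity:
    each subject emits from a subject-specific symbol pair on those edges
    and from a shared distribution elsewhere."""
    rng = np.random.default_rng(seed)
    out = []
    for sess in range(2):
        seqs = np.empty((n_subjects, n_edges, T), dtype=int)
        for k in range(n_subjects):
            for e in range(n_edges):
                if e in informative:
                    syms = [1 + 2 * k, 2 + 2 * k]
                    p = [0.8, 0.2] if e % 2 == 0 else [0.3, 0.7]
                    seqs[k, e] = rng.choice(syms, size=T, p=p)
                else:
                    seqs[k, e] = rng.choice([0, 1], size=T, p=[0.7, 0.3])
        out.append(seqs)
    return out[0], out[1]


@pytest.fixture(scope="module")
def toy_study():
    train, test = make_identity_cohort()
    models = fit_edge_models(train, state_grid=(2,), seed=0)
    L = edge_logliks(models, test)
    return {"train": train, "test": test, "models": models, "L": L}


class TestPdFeatureMatrix:
    def test_canonical_epoching_of_2991_windows(self):
        seq = np.zeros(2991, dtype=int)
        seq[:500] = 5                     # epoch 1 entirely label 5
        fm = pd_feature_matrix(seq)
        assert fm.shape == (6, 36)
        assert fm[0, 4] == 1.0 and fm[1:].sum() == 0.0

    def test_epoch_sizes_match_printed_partition(self):
        # label windows by epoch id to read the boundaries back
        seq = np.zeros(2991, dtype=int)
        bounds = [0, 500, 1000, 1500, 2000, 2500, 2991]
        for e in range(6):
            seq[bounds[e]:bounds[e + 1]] = e + 1
        fm = pd_feature_matrix(seq)
        for e in range(6):
            assert fm[e, e] == 1.0

    def test_constant_label_rows(self):
        fm = pd_feature_matrix(np.full(600, 5))
        assert np.allclose(fm[:, 4], 1.0)

    def test_all_zero_gives_zero_matrix(self):
        assert pd_feature_matrix(np.zeros(60, dtype=int)).sum() == 0.0

    def test_rows_sum_at_most_one(self):
        rng = np.random.default_rng(1)
        fm = pd_feature_matrix(rng.integers(0, 37, size=300))
        assert np.all(fm.sum(axis=1) <= 1.0 + 1e-12)


class TestRankingAndSelection:
    def test_informative_edges_ranked_first(self, toy_study):
        order, acc = rank_edges(toy_study["L"])
        assert set(order[:3]) == {0, 1, 2}
        assert np.all(acc[list({0, 1, 2})] >= acc[3:].max())

    def test_identity_free_edges_near_chance(self, toy_study):
        _, acc = rank_edges(toy_study["L"])
        assert acc[3:].max() <= 0.75     # 4 subjects -> chance 0.25

    def test_stepwise_reaches_perfect_accuracy(self, toy_study):
        selected, curve = stepwise_select(toy_study["L"])
        assert curve[-1] == 1.0
        assert np.all(np.diff(curve) > 0)
        assert set(selected) <= {0, 1, 2}

    def test_accuracy_curve_non_decreasing_on_noise(self):
        rng = np.random.default_rng(2)
        L = rng.normal(size=(10, 5, 5))
        _, curve = stepwise_select(L)
        assert np.all(np.diff(curve) > 0)

    def test_permuting_subjects_permutes_similarity(self, toy_study):
        L = toy_study["L"]
        sim = similarity_matrix(L, [0, 1, 2])
        perm = np.array([2, 0, 3, 1])
        sim_p = similarity_matrix(L[:, perm][:, :, perm], [0, 1, 2])
        assert np.allclose(sim_p, sim[perm][:, perm])


class TestThresholdsAndMatching:
    def test_threshold_moments_and_cutoff(self):
        rng = np.random.default_rng(3)
        n = 30
        sim = rng.normal(570, 15, (n, n))
        np.fill_diagonal(sim, rng.normal(1750, 100, n))
        dec = learn_thresholds(sim)
        assert dec.off_mean == pytest.approx(570, abs=5)
        assert dec.diag_mean == pytest.approx(1750, abs=60)
        assert dec.off_mean + 3 * dec.off_sd < dec.cutoff < \
            dec.diag_mean - 3 * dec.diag_sd

    def test_two_by_two_hand_computation(self):
        dec = learn_thresholds(np.array([[10.0, 0.0], [0.0, 10.0]]))
        assert dec.cutoff == pytest.approx(5.0)

    def test_inseparable_cohort_rejected(self):
        rng = np.random.default_rng(4)
        sim = rng.normal(0, 1, (10, 10))
        with pytest.raises(ValueError, match="not separable"):
            learn_thresholds(sim)

    def test_external_match_recovers_planted_identities(self, toy_study):
        """Cohort-2 made of re-realised subjects 1 and 3 plus two strangers
        (distinct symbol signatures) is matched exactly."""
        models, L = toy_study["models"], toy_study["L"]
        dec = learn_thresholds(similarity_matrix(L, [0, 1, 2]))
        fresh, _ = make_identity_cohort(seed=99)     # same identities, new data
        strangers, _ = make_identity_cohort(n_subjects=6, seed=123)
        cohort2 = np.stack([fresh[1], fresh[3], strangers[4], strangers[5]])
        L2 = edge_logliks(models, cohort2)
        matches, scores = external_match(L2, [0, 1, 2], dec)
        assert sorted(matches) == [(1, 0), (3, 1)]

    def test_differentiability_hand_computation(self):
        row = np.array([1750.0, 570.0, 580.0, 560.0])
        assert differentiability(row, 0) == pytest.approx(118.0)

    def test_differentiability_zero_when_self_at_mean(self):
        assert differentiability(np.array([5.0, 4.0, 5.0, 6.0]), 0) == 0.0

    def test_differentiability_guards(self):
        with pytest.raises(ValueError):
            differentiability(np.array([1.0, 1.0, 1.0, 1.0]), 0)
        with pytest.raises(ValueError):
            differentiability(np.array([1.0, 2.0, 3.0]), 0)


class TestSubnetworks:
    def test_fifteen_groups(self, toy_study):
        iu, ju = np.triu_indices(4, 1)
        nets = {0: "DMN", 1: "DMN", 2: "FP", 3: "CO"}
        out = subnetwork_performance(toy_study["L"], iu, ju, nets)
        assert len(out) == 15
        present = [g for g, v in out.items() if v is not None]
        assert ("DMN", "DMN") in present
        assert out[("SM", "O")] is None   # no edges in that group

    def test_unmapped_roi_rejected(self, toy_study):
        iu, ju = np.triu_indices(4, 1)
        with pytest.raises(ValueError):
            subnetwork_performance(toy_study["L"], iu, ju, {0: "DMN"})

    def test_identity_confined_to_group_tops_ranking(self, toy_study):
        """Edges 0-2 connect ROIs 0-2 (DMN/FP); the groups containing them
        outperform the identity-free CO edges."""
        iu, ju = np.triu_indices(4, 1)
        nets = {0: "DMN", 1: "DMN", 2: "FP", 3: "CO"}
        out = subnetwork_performance(toy_study["L"], iu, ju, nets)
        informative = out[("DMN", "DMN")]
        assert informative == 1.0 or out[("DMN", "FP")] == 1.0
        assert out[("DMN", "CO")] <= informative


class TestIdentificationAccuracy:
    def test_diagonal_dominant_scores(self):
        s = np.full((3, 3), -10.0)
        np.fill_diagonal(s, -1.0)
        assert identification_accuracy(s) == 1.0

    def test_single_subject_degenerate(self):
        assert identification_accuracy(np.array([[0.5]])) == 1.0
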