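"""Transition models, tiers, feature vectors and representative selection."""

import numpy as np
import pandas as pd
import pytest

from vocalpredict.config import ALPHABET, tier_thresholds
from vocalpredict.transitions import (EmptyModelError, TransitionModel,
                                      assign_tiers, cluster_trajectories,
                                      feature_names, pup_features,
                                      select_representative,
                                      transition_counts, transition_model)


def model_from(types, ids=None):
    types = np.asarray(types)
    ids = np.zeros(len(types), int) if ids is None else np.asarray(ids)
    return TransitionModel(ALPHABET, transition_counts(types, ids, ALPHABET))


class TestTransitionModel:
    def test_hand_counted_pairs(self):
        m = model_from(["Har", "Su", "Har", "Su"])
        i, j = ALPHABET.index("Har"), ALPHABET.index("Su")
        assert m.counts[i, j] == 2 and m.counts[j, i] == 1
        assert m.markov[i, j] == 1.0

    def test_deterministic_alternating_chain(self):
        m = model_from(["D", "F"] * 50)
        i, j = ALPHABET.index("D"), ALPHABET.index("F")
        assert m.markov[i, j] == 1.0 and m.markov[j, i] == 1.0
        assert m.proportions[i, j] == pytest.approx(50 / 99)

    def test_pairs_do_not_cross_sequence_boundaries(self):
        m = model_from(["D", "F", "F", "D"], ids=[0, 0, 1, 1])
        i, j = ALPHABET.index("D"), ALPHABET.index("F")
        assert m.counts[i, j] == 1 and m.counts[j, j] == 0
        assert m.counts.sum() == 2

    def test_zero_connections_raise(self):
        with pytest.raises(EmptyModelError):
            model_from(["D", "F"], ids=[0, 1])

    def test_invariants_on_cohort(self, segmented_calls):
        m = transition_model(segmented_calls)
        assert m.proportions.sum() == pytest.approx(1.0)
        rows = m.markov.sum(axis=1)
        assert np.allclose(rows[~m.row_empty], 1.0)
        assert np.allclose(rows[m.row_empty], 0.0)

    def test_estimated_markov_matrix_converges_to_generator(self):
        from vocalpredict.simulate import GenotypeProfile, PI_DUP, \
            _mixture_rows, simulate_pup_session
        T = _mixture_rows(PI_DUP, 0.15)
        profile = GenotypeProfile("Dup", {12: 100_000.0}, PI_DUP, T)
        df = simulate_pup_session(profile, 12, np.random.default_rng(0),
                                  with_contours=False)
        m = model_from(df["call_type"], df["truth_sequence_id"])
        assert m.counts.sum() >= 80_000
        est = m.markov[~m.row_empty]
        assert np.max(np.abs(est - T[~m.row_empty])) < 0.02


class TestTiers:
    def test_printed_threshold_values(self):
        taus = tier_thresholds((1.5, 2.0, 2.5), 13)
        assert round(taus[0], 4) == 0.1154
        assert round(taus[2], 4) == 0.1923

    def test_chance_level_cell_gets_no_tier(self):
        C = np.ones((13, 13), int)   # every Markov probability exactly 1/13
        m = TransitionModel(ALPHABET, C)
        assert (assign_tiers(m) == 0).all()

    def test_tiers_monotone_in_probability(self, rng):
        C = rng.integers(0, 50, size=(13, 13))
        C[0, 0] += 1
        m = TransitionModel(ALPHABET, C)
        tiers = assign_tiers(m)
        taus = tier_thresholds()
        for level, tau in enumerate(sorted(taus), start=1):
            assert (tiers[m.markov > tau] >= level).all()
        assert (tiers[m.markov <= min(taus)] == 0).all()


class TestPupFeatures:
    def test_two_harmonic_calls(self):
        f = pup_features(np.array(["Har", "Har"]), np.zeros(2, int))
        assert f["Har(N)"] == 2 and f["Har(P)"] == 1.0
        assert f["Har_Har(MP)"] == 1.0
        assert f["Su_Su(N)"] == 0

    def test_feature_vector_has_533_names(self):
        assert len(feature_names()) == 13 + 13 + 169 * 3 == 533
        f = pup_features(np.array(["D"]), np.zeros(1, int))
        assert len(f) == 533

    def test_matches_brute_force_on_five_calls(self):
        types = np.array(["Har", "D", "D", "F", "Har"])
        ids = np.array([0, 0, 0, 1, 1])
        f = pup_features(types, ids)
        # hand-count: pairs within sequences: Har-D, D-D, F-Har
        assert f["Har_D(N)"] == 1 and f["D_D(N)"] == 1 and f["F_Har(N)"] == 1
        assert f["D_F(N)"] == 0                      # crosses the boundary
        assert f["Har_D(P)"] == pytest.approx(1 / 3)
        assert f["D_D(MP)"] == 1.0   # the only within-sequence pair from D
        assert f["D(N)"] == 2 and f["D(P)"] == pytest.approx(0.4)
        assert np.isnan(f["Su_Su(MP)"])              # Su never emitted

    def test_absent_pairs_zero_but_missing_mp_flagged(self):
        f = pup_features(np.array(["D", "D"]), np.zeros(2, int))
        assert f["F_F(N)"] == 0 and f["F_F(P)"] == 0.0
        assert np.isnan(f["F_F(MP)"])


class TestRepresentative:
    def _features(self, rng, n=20):
        from vocalpredict.simulate import default_profiles, simulate_pup_session
        profile = default_profiles()["WT"]
        rows = {}
        for i in range(n):
            df = simulate_pup_session(profile, 12, rng, with_contours=False)
            rows[f"p{i:02d}"] = pup_features(df["call_type"].to_numpy(),
                                             df["truth_sequence_id"].to_numpy())
        return pd.DataFrame(rows).T.rename_axis("pup_id").reset_index()

    def test_single_pup_is_its_own_representative(self, rng):
        feats = self._features(rng, n=1)
        assert select_representative(feats) == "p00"

    def test_matches_exhaustive_minimizer(self, rng):
        from vocalpredict.transitions import _block_columns, FEATURE_BLOCKS
        feats = self._features(rng, n=20)
        picked = select_representative(feats)
        # independent brute force over pups
        indexed = feats.set_index("pup_id")
        dists = {}
        for pup in indexed.index:
            d = 0.0
            for block in FEATURE_BLOCKS:
                cols = _block_columns(block, ALPHABET)
                X = indexed[cols].to_numpy(float)
                sd = X.std(axis=0)
                sd[sd == 0] = 1.0
                Z = (X - X.mean(axis=0)) / sd
                med = np.median(Z, axis=0)
                z = Z[list(indexed.index).index(pup)]
                d += float(np.sqrt(((z - med) ** 2).sum()))
            dists[pup] = d
        assert picked == min(sorted(dists), key=dists.get)


class TestClusterTrajectories:
    def test_single_cluster_only_diagonal(self):
        M = cluster_trajectories(np.zeros(10, int), np.zeros(10, int),
                                 n_clusters=4)
        assert M[0, 0] == 9 and M.sum() == 9

    def test_alternating_clusters(self):
        M = cluster_trajectories(np.array([1, 2, 1, 2]), np.zeros(4, int),
                                 n_clusters=3)
        assert M[1, 2] == 2 and M[2, 1] == 1

    def test_unlabeled_calls_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            cluster_trajectories(np.array([0, -1, 1]), np.zeros(3, int))

    def test_generator_diagonal_bias_differs_by_genotype(self):
        # WT concentrates on the simple-call cluster (2): its within-cluster
        # share of transitions should exceed Dup's in most replicates
        from vocalpredict.simulate import default_profiles, \
            simulate_pup_session, TYPE_CLUSTER
        profiles = default_profiles()
        rng = np.random.default_rng(0)
        wins = 0
        reps = 20
        for _ in range(reps):
            shares = {}
            for geno in ("WT", "Dup"):
                df = simulate_pup_session(profiles[geno], 12, rng,
                                          with_contours=False)
                labels = np.array([TYPE_CLUSTER[t] for t in df["call_type"]])
                M = cluster_trajectories(labels,
                                         df["truth_sequence_id"].to_numpy(), 4)
                shares[geno] = M[2, 2] / M.sum()
            wins += shares["WT"] > shares["Dup"]
        assert wins >= int(0.9 * reps)
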