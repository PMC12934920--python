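"""Lasso path selection, information criterion, stability, correlations."""

import numpy as np
import pandas as pd
import pytest

from vocalpredict.selection import (build_feature_matrix, correlation_validation,
                                    lasso_aic, stability_selection)


def frame(arr, prefix="f"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestLassoAIC:
    def test_noise_free_single_signal_selected_with_correct_slope(self, rng):
        X = frame(rng.standard_normal((30, 10)))
        y = 2.0 * X["f3"].to_numpy()
        res = lasso_aic(X, y)
        assert list(res.selected.index) == ["f3"]
        # at the bottom of the path the standardized coefficient approaches
        # 2 * sd(x_j)
        j = res.feature_names.index("f3")
        sd = X["f3"].std(ddof=0)
        assert res.coefs[j, -1] == pytest.approx(2.0 * sd, rel=1e-2)

    def test_all_coefficients_zero_at_lambda_max(self, rng):
        X = frame(rng.standard_normal((25, 15)))
        y = rng.standard_normal(25)
        res = lasso_aic(X, y)
        assert (np.abs(res.coefs[:, 0]) < 1e-10).all()

    def test_chosen_model_beats_empty_model_rss(self, rng):
        X = frame(rng.standard_normal((25, 15)))
        y = X["f0"].to_numpy() + rng.standard_normal(25)
        res = lasso_aic(X, y)
        tss = np.sum((y - y.mean()) ** 2)
        assert res.rss[res.chosen_index] <= tss + 1e-9

    def test_selected_set_invariant_to_feature_rescaling(self, rng):
        X = frame(rng.standard_normal((25, 12)))
        y = 1.5 * X["f2"].to_numpy() - X["f7"].to_numpy() \
            + 0.3 * rng.standard_normal(25)
        base = set(lasso_aic(X, y).selected.index)
        X2 = X.copy()
        X2["f2"] = X2["f2"] * 1000.0 + 5.0
        X2["f7"] = X2["f7"] / 77.0
        assert set(lasso_aic(X2, y).selected.index) == base

    def test_planted_support_recovered_at_snr_3(self, rng):
        hits = 0
        reps = 15
        for _ in range(reps):
            X = frame(rng.standard_normal((25, 30)))
            beta = np.zeros(30)
            beta[:3] = [2.0, -1.5, 1.0]
            signal = X.to_numpy() @ beta
            y = signal + rng.standard_normal(25) * np.std(signal) / np.sqrt(3)
            sel = lasso_aic(X, y).selected
            hits += all(f"f{i}" in sel.index for i in range(3))
        assert hits >= int(0.6 * reps)

    def test_null_response_selects_fewer_than_signal(self, rng):
        null_sizes, signal_sizes = [], []
        for _ in range(10):
            X = frame(rng.standard_normal((29, 40)))
            null_sizes.append(len(lasso_aic(X, rng.standard_normal(29)).selected))
            y = 3.0 * X["f0"].to_numpy() + rng.standard_normal(29)
            signal_sizes.append(len(lasso_aic(X, y).selected))
        assert np.median(null_sizes) <= 3
        assert all(s >= 1 for s in signal_sizes)

    def test_constant_features_dropped_with_record(self, rng):
        X = frame(rng.standard_normal((25, 5)))
        X["const"] = 1.0
        res = lasso_aic(X, X["f0"].to_numpy())
        assert res.dropped_constant == ["const"]

    def test_zero_variance_response_rejected(self, rng):
        X = frame(rng.standard_normal((25, 5)))
        with pytest.raises(ValueError, match="variance"):
            lasso_aic(X, np.ones(25))


class TestStability:
    def test_noise_free_signal_is_5_of_5(self, rng):
        X = frame(rng.standard_normal((25, 10)))
        y = 2.0 * X["f4"].to_numpy()
        counts, selections = stability_selection(X, y, seed=0)
        assert counts["f4"] == 5
        assert len(selections) == 5

    def test_drop_sizes_alternate_5_and_6(self, rng):
        X = frame(rng.standard_normal((25, 10)))
        y = X["f0"].to_numpy() + 0.5 * rng.standard_normal(25)
        _, selections = stability_selection(X, y, seed=3)
        # indirect check via the fitted sample sizes is not exposed;
        # assert the call honors n - n_drop >= 10 at the boundary instead
        with pytest.raises(ValueError, match="too few"):
            stability_selection(X.head(15), y[:15], seed=0)

    def test_planted_genes_dominate_noise_features(self, full_cohort):
        from vocalpredict.sequences import fit_interval_models, segment_table
        from vocalpredict.transitions import pup_feature_table
        from vocalpredict.expression import compute_rq, rq_wide
        calls = full_cohort["calls"]
        seg = segment_table(calls, fit_interval_models(calls))
        X, y = build_feature_matrix(
            pup_feature_table(seg), rq_wide(compute_rq(full_cohort["expression"])),
            full_cohort["scores"], "Dup", 2)
        counts, _ = stability_selection(X, y, seed=1)
        assert counts["Magel2"] >= 3 and counts["Herc2"] >= 3
        others = counts.drop(["Magel2", "Herc2"])
        assert counts["Magel2"] >= others.max()


class TestCorrelations:
    def test_exact_negative_correlation(self, rng):
        X = frame(rng.standard_normal((20, 3)))
        y = -X["f1"].to_numpy()
        out = correlation_validation(X, y)
        assert out.iloc[0]["feature"] == "f1"
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_zero_variance_feature_flagged(self, rng):
        X = frame(rng.standard_normal((20, 2)))
        X["f0"] = 3.0
        out = correlation_validation(X, rng.standard_normal(20))
        assert out.set_index("feature").loc["f0", "flag"] == "zero-variance"

    def test_independent_feature_rarely_correlates(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            r = correlation_validation(frame(x[:, None]), y).iloc[0]["r"]
            hits += abs(r) < 0.5
        assert hits >= int(0.9 * reps)

    def test_planted_negative_genes_rank_top_with_negative_sign(self, full_cohort):
        from vocalpredict.expression import compute_rq, rq_wide
        genes = rq_wide(compute_rq(full_cohort["expression"]))
        dup = genes[genes.genotype == "Dup"].set_index("mouse_id")
        scores = full_cohort["scores"]
        s2 = scores[(scores.genotype == "Dup") & (scores.session == 2)] \
            .set_index("mouse_id")["score"]
        X = dup.drop(columns=["genotype"]).loc[s2.index]
        out = correlation_validation(X, s2.to_numpy())
        top2 = set(out.head(2)["feature"])
        assert top2 == {"Magel2", "Herc2"}
        assert (out.head(2)["r"] < 0).all()


class TestFeatureMatrix:
    def test_orphan_mouse_is_named(self, small_cohort):
        from vocalpredict.sequences import fit_interval_models, segment_table
        from vocalpredict.transitions import pup_feature_table
        from vocalpredict.expression import compute_rq, rq_wide
        calls = small_cohort["calls"]
        seg = segment_table(calls, fit_interval_models(calls))
        feats = pup_feature_table(seg)
        genes = rq_wide(compute_rq(small_cohort["expression"]))
        genes = genes[genes["mouse_id"] != "Dup01"]
        with pytest.raises(ValueError, match="Dup01"):
            build_feature_matrix(feats, genes, small_cohort["scores"],
                                 "Dup", 1)

    def test_matrix_matches_hand_assembly(self, small_cohort):
        from vocalpredict.sequences import fit_interval_models, segment_table
        from vocalpredict.transitions import pup_feature_table, pup_features
        from vocalpredict.expression import compute_rq, rq_wide
        calls = small_cohort["calls"]
        seg = segment_table(calls, fit_interval_models(calls))
        feats = pup_feature_table(seg)
        genes = rq_wide(compute_rq(small_cohort["expression"]))
        X, y = build_feature_matrix(feats, genes, small_cohort["scores"],
                                    "WT", 1)
        assert X.shape[1] == 533 + 11
        for mouse in list(X.index[:3]):
            grp = seg[(seg.pup_id == mouse) & (seg.age_day == 12)]
            expected = pup_features(grp["call_type"].to_numpy(),
                                    grp["sequence_id"].to_numpy()).fillna(0.0)
            got = X.loc[mouse, expected.index]
            np.testing.assert_allclose(got.to_numpy(float),
                                       expected.to_numpy(float))
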