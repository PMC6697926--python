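"""LUMP score and agreement/quantile machinery against hand-computed values."""

import numpy as np
import pandas as pd
import pytest

import purityforest as pf

from conftest import make_purity


def betas(rows: dict, samples) -> pf.BetaMatrix:
    return pf.BetaMatrix(pd.DataFrame(rows, index=samples).T)


class TestLumpScore:
    def test_panel_at_scale_value_scores_one(self):
        m = betas({"cg1": [0.85, 0.0], "cg2": [0.85, 0.0]}, ["s1", "s2"])
        table, counts = pf.lump_score(m, ["cg1", "cg2"], scale=0.85)
        assert table.purity["s1"] == pytest.approx(1.0, abs=1e-12)
        assert table.purity["s2"] == 0.0  # fully immune-infiltrated limit
        assert table.source == "LUMP"
        assert counts.tolist() == [2, 2]

    def test_hand_arithmetic_three_probe_panel(self):
        m = betas({"cg1": [0.2], "cg2": [0.4], "cg3": [0.6]}, ["s1"])
        table, _ = pf.lump_score(m, ["cg1", "cg2", "cg3"], scale=0.85)
        assert table.purity["s1"] == pytest.approx(0.4 / 0.85, abs=1e-12)

    def test_cap_and_scale_behaviour(self):
        m = betas({"cg1": [0.9]}, ["s1"])
        capped, _ = pf.lump_score(m, ["cg1"], scale=0.85, cap=True)
        assert capped.purity["s1"] == 1.0
        raw, _ = pf.lump_score(m, ["cg1"], scale=1.0, cap=False)
        assert raw.purity["s1"] == pytest.approx(0.9, abs=1e-12)
        # doubling the scale halves uncapped scores
        half, _ = pf.lump_score(m, ["cg1"], scale=2.0, cap=False)
        assert half.purity["s1"] == pytest.approx(0.45, abs=1e-12)
        # a sub-1 scale without the cap violates the purity range
        with pytest.raises(pf.ValidationError):
            pf.lump_score(m, ["cg1"], scale=0.85, cap=False)

    def test_monotone_in_every_panel_beta(self):
        rng = np.random.default_rng(1)
        base = rng.random(4)
        m0 = betas({f"cg{i}": [b] for i, b in enumerate(base)}, ["s"])
        t0, _ = pf.lump_score(m0, [f"cg{i}" for i in range(4)], cap=False)
        bumped = base.copy()
        bumped[2] = min(1.0, bumped[2] + 0.1)
        m1 = betas({f"cg{i}": [b] for i, b in enumerate(bumped)}, ["s"])
        t1, _ = pf.lump_score(m1, [f"cg{i}" for i in range(4)], cap=False)
        assert t1.purity["s"] >= t0.purity["s"]

    def test_empty_panel_intersection_rejected(self):
        m = betas({"cg1": [0.5]}, ["s1"])
        with pytest.raises(pf.ValidationError, match="panel"):
            pf.lump_score(m, ["cgX"])


class TestEvaluatePredictions:
    def test_identity(self):
        a = make_purity([0.2, 0.5, 0.9], source="RF_PREDICTED")
        b = make_purity([0.2, 0.5, 0.9], source="ABSOLUTE")
        rep = pf.evaluate_predictions(a, b)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.mse == 0.0
        assert rep.median_abs_diff == 0.0
        assert rep.n == 3

    def test_anticorrelated(self):
        vals = [0.1, 0.4, 0.8]
        a = make_purity(vals, source="RF_PREDICTED")
        b = make_purity([1 - v for v in vals], source="ABSOLUTE")
        assert pf.evaluate_predictions(a, b).pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_five_sample_hand_computation(self):
        va = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        vb = np.array([0.2, 0.25, 0.55, 0.65, 0.8])
        a = make_purity(va, source="RF_PREDICTED")
        b = make_purity(vb, source="ESTIMATE")
        rep = pf.evaluate_predictions(a, b)
        d = va - vb
        r_hand = np.sum((va - va.mean()) * (vb - vb.mean())) / np.sqrt(
            np.sum((va - va.mean()) ** 2) * np.sum((vb - vb.mean()) ** 2)
        )
        assert rep.pearson_r == pytest.approx(r_hand, abs=1e-12)
        assert rep.mse == pytest.approx(np.mean(d**2), abs=1e-12)
        assert rep.median_abs_diff == pytest.approx(np.median(np.abs(d)), abs=1e-12)

    def test_symmetry(self):
        a = make_purity([0.1, 0.6, 0.8, 0.3], source="RF_PREDICTED")
        b = make_purity([0.2, 0.4, 0.9, 0.5], source="LUMP")
        ab, ba = pf.evaluate_predictions(a, b), pf.evaluate_predictions(b, a)
        assert ab.pearson_r == pytest.approx(ba.pearson_r, abs=1e-15)
        assert ab.mse == pytest.approx(ba.mse, abs=1e-15)
        assert ab.median_abs_diff == pytest.approx(ba.median_abs_diff, abs=1e-15)

    def test_too_few_shared_samples(self):
        a = make_purity([0.1, 0.2], source="RF_PREDICTED")
        b = make_purity([0.1, 0.2], source="ABSOLUTE")
        with pytest.raises(pf.ValidationError, match="shared"):
            pf.evaluate_predictions(a, b)

    def test_zero_variance_flags_r_but_keeps_mse(self):
        a = make_purity([0.5, 0.5, 0.5], source="RF_PREDICTED")
        b = make_purity([0.2, 0.5, 0.9], source="ABSOLUTE")
        rep = pf.evaluate_predictions(a, b)
        assert rep.zero_variance and np.isnan(rep.pearson_r)
        assert rep.mse == pytest.approx(np.mean((0.5 - np.array([0.2, 0.5, 0.9])) ** 2))


class TestPairwiseCorrelations:
    def test_identical_tables_give_unit_matrix(self):
        tables = [make_purity([0.1, 0.5, 0.9], source=s)
                  for s in ("ABSOLUTE", "ESTIMATE", "LUMP")]
        mat = pf.pairwise_correlations(tables)
        assert np.allclose(mat.to_numpy(), 1.0)

    def test_disjoint_tables_flagged_missing(self):
        t1 = make_purity([0.1, 0.2, 0.3], ids=["a1", "a2", "a3"], source="ABSOLUTE")
        t2 = make_purity([0.1, 0.2, 0.3], ids=["b1", "b2", "b3"], source="ESTIMATE")
        mat = pf.pairwise_correlations([t1, t2])
        assert np.isnan(mat.iloc[0, 1]) and np.isnan(mat.iloc[1, 0])
        assert mat.iloc[0, 0] == 1.0

    def test_rf_tracks_truth_better_than_lump(self, small_cohort, small_model):
        pred, _ = pf.predict_purity(
            small_model, small_cohort.betas.restrict_samples(small_model.test_ids)
        )
        lump, _ = pf.lump_score(small_cohort.betas, small_cohort.lump_panel)
        mat = pf.pairwise_correlations(
            [small_cohort.truth.restrict(small_model.test_ids), pred, lump]
        )
        assert mat.loc["SYNTHETIC_TRUTH", "RF_PREDICTED"] > mat.loc["SYNTHETIC_TRUTH", "LUMP"]


class TestQuantiles:
    def test_decile_sample_median_is_055(self):
        t = make_purity(np.arange(0.1, 1.05, 0.1), group=["g"] * 10)
        table = pf.purity_quantiles_by_group(t, probs=(0.5,))
        assert table.values.loc["g", 0.5] == pytest.approx(0.55, abs=1e-12)

    def test_rows_non_decreasing_and_identical_groups_match(self):
        vals = [0.2, 0.4, 0.6, 0.8, 0.2, 0.4, 0.6, 0.8]
        t = make_purity(vals, group=["a"] * 4 + ["b"] * 4)
        table = pf.purity_quantiles_by_group(t)
        assert (table.values.diff(axis=1).iloc[:, 1:] >= -1e-15).all().all()
        assert np.allclose(table.values.loc["a"], table.values.loc["b"])
        assert table.n_per_group.tolist() == [4, 4]

    def test_out_of_range_prob_rejected(self):
        t = make_purity([0.1, 0.2], group=["g", "g"])
        with pytest.raises(pf.ValidationError):
            pf.purity_quantiles_by_group(t, probs=(0.0, 0.5))

    def test_missing_groups_rejected(self):
        t = make_purity([0.1, 0.2])
        with pytest.raises(pf.ValidationError, match="group"):
            pf.purity_quantiles_by_group(t)

    def test_small_group_flagged(self):
        t = make_purity([0.1, 0.2, 0.3, 0.4, 0.5], group=["a"] * 3 + ["b"] * 2)
        table = pf.purity_quantiles_by_group(t)
        assert table.small_groups == ("b",)


class TestAbsDifferenceSummary:
    def test_identity_and_offset(self):
        a = make_purity([0.2, 0.4, 0.6], source="RF_PREDICTED")
        assert pf.abs_difference_summary(a, a)["median"] == 0.0
        b = make_purity([0.25, 0.45, 0.65], source="ABSOLUTE")
        assert pf.abs_difference_summary(a, b)["median"] == pytest.approx(0.05, abs=1e-12)

    def test_four_sample_hand_computation(self):
        a = make_purity([0.1, 0.5, 0.6, 0.9], source="RF_PREDICTED")
        b = make_purity([0.2, 0.45, 0.7, 0.8], source="ESTIMATE")
        out = pf.abs_difference_summary(a, b)
        diffs = np.abs(np.array([0.1, 0.5, 0.6, 0.9]) - np.array([0.2, 0.45, 0.7, 0.8]))
        assert out["median"] == pytest.approx(np.median(diffs), abs=1e-12)
        assert out["mean"] == pytest.approx(np.mean(diffs), abs=1e-12)
        assert sum(out["histogram_counts"]) == 4

    def test_no_shared_samples_rejected(self):
        a = make_purity([0.5], ids=["a"], source="RF_PREDICTED")
        b = make_purity([0.5], ids=["b"], source="ABSOLUTE")
        with pytest.raises(pf.ValidationError):
            pf.abs_difference_summary(a, b)
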