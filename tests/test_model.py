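"""Partitioning, importance ranking, OOB sweep, end-to-end training."""

import numpy as np
import pandas as pd
import pytest

import purityforest as pf

from conftest import make_purity


class TestPartition:
    def test_seventy_thirty_split(self):
        labels = make_purity(np.linspace(0.1, 0.9, 100))
        part = pf.partition_samples(labels, 0.70, seed=1)
        assert len(part.train_ids) == 70 and len(part.test_ids) == 30
        assert not set(part.train_ids) & set(part.test_ids)

    def test_group_stratification_is_balanced(self):
        labels = make_purity(
            np.linspace(0.2, 0.8, 100), group=["a"] * 50 + ["b"] * 50
        )
        part = pf.partition_samples(labels, 0.70, seed=2)
        train = set(part.train_ids)
        per_group = [sum(1 for s in train if labels.group[s] == g) for g in ("a", "b")]
        assert per_group == [35, 35]
        assert part.stratify_on == "group"

    def test_same_seed_reproduces_partition(self):
        labels = make_purity(np.linspace(0, 1, 40))
        a = pf.partition_samples(labels, 0.7, seed=5)
        b = pf.partition_samples(labels, 0.7, seed=5)
        assert a == b
        c = pf.partition_samples(labels, 0.7, seed=6)
        assert a.train_ids != c.train_ids

    def test_singleton_stratum_falls_back_to_pooled(self):
        labels = make_purity([0.1, 0.2, 0.3, 0.9], group=["a", "a", "a", "b"])
        part = pf.partition_samples(labels, 0.5, seed=0)
        assert part.pooled_fallback
        assert part.stratify_on == "none"


class TestCandidateCounts:
    def test_reproduces_the_856_probe_model_size(self):
        # 1% of a 20%-screened 450K array (85,600 probes) -> 856 probes
        assert pf.candidate_counts(85_600, (0.001, 0.01, 0.05, 0.10)) == (86, 856, 4280, 8560)

    def test_colliding_fractions_are_deduplicated(self):
        # on a tiny screened set several fractions round to the same count
        assert pf.candidate_counts(100, (0.001, 0.01, 0.05, 0.10)) == (1, 5, 10)

    def test_fraction_out_of_range(self):
        with pytest.raises(pf.ValidationError):
            pf.candidate_counts(100, (0.5, 1.5))

    def test_non_increasing_fractions_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.candidate_counts(100, (0.5, 0.1))


class TestInitialForest:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_probes_dominate_importance(self, seed):
        """50 informative among 5,000 probes: at least 45 land in the top 100."""
        cfg = pf.SimulationConfig(
            n_probes=5000, n_informative=50, n_entity_probes=0, lump_panel_size=0,
            samples_per_entity=50, seed=seed,
        )
        cohort = pf.simulate_cohort(cfg)
        ranking = pf.train_initial_forest(cohort.betas, cohort.truth, seed=seed)
        top100 = set(ranking.probe_ids[:100])
        assert len(top100 & set(cohort.informative_probes)) >= 45

    def test_zero_variance_outcome_is_flagged(self, small_cohort):
        sub = small_cohort.betas.restrict_probes(list(small_cohort.betas.probe_ids[:50]))
        y = make_purity([0.5] * 20, ids=list(sub.sample_ids[:20]))
        ranking = pf.train_initial_forest(sub.restrict_samples(y.sample_ids), y, n_trees=20)
        assert any("zero-variance" in note for note in ranking.notes)

    def test_fixed_seed_reproduces_ranking(self, small_cohort):
        sub = small_cohort.betas.restrict_probes(list(small_cohort.betas.probe_ids[:100]))
        y = small_cohort.truth
        a = pf.train_initial_forest(sub, y, n_trees=50, seed=7)
        b = pf.train_initial_forest(sub, y, n_trees=50, seed=7)
        assert a.probe_ids == b.probe_ids

    def test_sample_mismatch_rejected(self, small_cohort):
        y = make_purity([0.5, 0.6], ids=["nope1", "nope2"])
        with pytest.raises(pf.ValidationError):
            pf.train_initial_forest(small_cohort.betas, y)


class TestSweep:
    def test_single_full_fraction_degenerates(self, small_cohort):
        sub = small_cohort.betas.restrict_probes(list(small_cohort.informative_probes[:30]))
        ranking = pf.train_initial_forest(sub, small_cohort.truth, n_trees=50, seed=3)
        sweep = pf.sweep_candidates(sub, small_cohort.truth, ranking, fractions=(1.0,),
                                    n_trees=50, seed=3)
        assert sweep.probe_counts == (30,)
        assert sweep.chosen == 0

    def test_chosen_minimizes_oob(self, small_model):
        errors = [e for _, e in small_model.candidate_record]
        assert errors[small_model.selected_candidate] == min(errors)

    def test_chosen_candidate_contains_planted_signal(self):
        """With 50 planted probes among 2,000 and candidate sizes above the
        planted count, the OOB-chosen probe set keeps >= 90% of the planted."""
        cfg_sim = pf.SimulationConfig(
            n_probes=2000, n_informative=50, n_entity_probes=0, lump_panel_size=0,
            samples_per_entity=40, seed=13,
        )
        cohort = pf.simulate_cohort(cfg_sim)
        cfg = pf.TrainConfig(seed=13, candidate_fractions=(0.25, 0.5, 1.0))
        model = pf.train_purity_model(cohort.betas, cohort.truth, cfg)
        kept = set(model.final_probes) & set(cohort.informative_probes)
        assert len(kept) >= 0.9 * len(cohort.informative_probes)


class TestTrainPurityModel:
    def test_recovers_truth_on_small_cohort(self, small_cohort, small_model):
        pred, _ = pf.predict_purity(
            small_model, small_cohort.betas.restrict_samples(small_model.test_ids)
        )
        report = pf.evaluate_predictions(pred, small_cohort.truth.restrict(small_model.test_ids))
        assert report.pearson_r >= 0.90
        assert report.median_abs_diff <= 0.05

    def test_wider_screening_not_worse_when_signal_is_abundant(self):
        """When the informative probes outnumber the 5% screen, screening at
        20% keeps an OOB error no worse than screening at 5% -- the ordering
        reported for the dip screen on real cohorts."""
        cfg_sim = pf.SimulationConfig(
            n_probes=1200, n_informative=150, n_entity_probes=30, lump_panel_size=0,
            samples_per_entity=30, seed=17,
        )
        cohort = pf.simulate_cohort(cfg_sim)
        res = {}
        for frac in (0.20, 0.05):
            cfg = pf.TrainConfig(seed=17, screening_fraction=frac)
            model = pf.train_purity_model(cohort.betas, cohort.truth, cfg)
            res[frac] = model.candidate_record[model.selected_candidate][1]
        assert res[0.20] <= res[0.05]

    def test_empty_labels_rejected(self, small_cohort):
        empty = pf.PurityTable(purity=pd.Series(dtype=float), source="ABSOLUTE")
        with pytest.raises(pf.ValidationError, match="empty"):
            pf.train_purity_model(small_cohort.betas, empty)

    def test_disjoint_samples_rejected(self, small_cohort):
        y = make_purity([0.4, 0.6, 0.8], ids=["x1", "x2", "x3"])
        with pytest.raises(pf.ValidationError, match="overlap"):
            pf.train_purity_model(small_cohort.betas, y)

    def test_candidate_record_and_probes_are_consistent(self, small_model):
        count = small_model.candidate_record[small_model.selected_candidate][0]
        assert len(small_model.final_probes) == count
        assert len(set(small_model.final_probes)) == count


class TestPredict:
    def test_training_matrix_predictions_match_forest_fit(self, small_model, small_cohort):
        train = small_cohort.betas.restrict_samples(small_model.train_ids)
        pred, imputed = pf.predict_purity(small_model, train)
        assert (imputed == 0).all()
        design = train.values.loc[list(small_model.final_probes)].T.to_numpy()
        direct = np.clip(small_model.ensemble.predict(design), 0, 1)
        assert np.array_equal(pred.purity.to_numpy(), direct)
        assert pred.purity.between(0, 1).all()
        assert pred.source == "RF_PREDICTED"

    def test_copy_of_training_sample_gets_its_fitted_value(self, small_model, small_cohort):
        sid = small_model.train_ids[0]
        copy = small_cohort.betas.restrict_samples([sid])
        copy.values.columns = ["copycat"]
        pred, _ = pf.predict_purity(small_model, pf.BetaMatrix(copy.values))
        orig, _ = pf.predict_purity(small_model, small_cohort.betas.restrict_samples([sid]))
        assert pred.purity.iloc[0] == pytest.approx(orig.purity.iloc[0], abs=1e-12)

    def test_pure_tumor_scores_above_pure_stroma(self, small_cohort, small_model):
        tumor, stroma, *_ = pf.draw_reference_profiles(small_cohort.config)
        frame = pd.DataFrame({
            "pure_tumor": tumor["entity1"],
            "pure_stroma": stroma,
        })
        pred, _ = pf.predict_purity(small_model, pf.BetaMatrix(frame))
        assert pred.purity["pure_tumor"] > pred.purity["pure_stroma"]

    def test_absent_probes_are_imputed_and_reported(self, small_model, small_cohort):
        keep = list(small_model.final_probes[: len(small_model.final_probes) // 2])
        sub = small_cohort.betas.restrict_probes(keep).restrict_samples(
            list(small_cohort.betas.sample_ids[:5])
        )
        pred, imputed = pf.predict_purity(small_model, sub)
        expect = 1 - len(keep) / len(small_model.final_probes)
        assert imputed.iloc[0] == pytest.approx(expect, abs=1e-12)
        assert pred.purity.between(0, 1).all()

    def test_zero_probe_overlap_rejected(self, small_model):
        stranger = pf.BetaMatrix(pd.DataFrame([[0.5]], index=["cgX"], columns=["s"]))
        with pytest.raises(pf.ValidationError, match="none of the model probes"):
            pf.predict_purity(small_model, stranger)
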