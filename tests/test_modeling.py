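"""Fold construction, grid search, consensus parameters, bundles, pipeline."""

import numpy as np
import pytest

from aippred import synthetic
from aippred.exceptions import (ConfigurationError, ParameterError,
                                PipelineError)
from aippred.features import encode_dataset
from aippred.evaluation import confusion, threshold_metrics
from aippred.modeling import (CVPlan, HyperParams, ModelBundle,
                              PipelineConfig, build_estimator,
                              consensus_params, grid_search, make_folds,
                              predict, run_pipeline, train_final,
                              train_test_split_dataset, tune_cutoff)
from aippred.selection import FeatureSet


class TestMakeFolds:
    def test_exact_stratification_when_divisible(self):
        labels = np.array([1] * 40 + [0] * 60)
        fold_of = make_folds(100, labels, CVPlan(folds=5, repeats=1, seed=0))[0]
        for f in range(5):
            mask = fold_of == f
            assert mask.sum() == 20
            assert labels[mask].sum() == 8  # 8 positives, 12 negatives

    def test_deterministic(self):
        labels = np.array([1] * 30 + [0] * 30)
        a = make_folds(60, labels, CVPlan(folds=5, repeats=3, seed=4))
        b = make_folds(60, labels, CVPlan(folds=5, repeats=3, seed=4))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_repeats_produce_distinct_partitions(self):
        labels = np.array([1] * 30 + [0] * 30)
        reps = make_folds(60, labels, CVPlan(folds=5, repeats=10, seed=0))
        distinct = {tuple(r) for r in reps}
        assert len(distinct) >= 9

    def test_every_record_in_exactly_one_test_fold(self):
        labels = np.array([1] * 25 + [0] * 35)
        for fold_of in make_folds(60, labels, CVPlan(folds=4, repeats=2, seed=1)):
            assert set(fold_of) == {0, 1, 2, 3}
            assert len(fold_of) == 60

    def test_class_smaller_than_folds_rejected(self):
        labels = np.array([1] * 3 + [0] * 57)
        with pytest.raises(ParameterError):
            make_folds(60, labels, CVPlan(folds=5, repeats=1, seed=0))


class TestGridSearch:
    def test_single_point_grid_returned_everywhere(self, strong_data):
        matrix = encode_dataset(strong_data, "aac")
        grid = {"ntree": (50,), "mtry": (2,), "nsplit": (3,)}
        gs = grid_search(matrix, strong_data.labels, "RF", grid,
                         CVPlan(folds=3, repeats=2, seed=0))
        expected = HyperParams("RF", ntree=50, mtry=2, nsplit=3)
        assert gs.per_repeat_params == [expected, expected]

    def test_separable_synthetic_auc(self, strong_data, small_grid):
        matrix = encode_dataset(strong_data, "dpc")
        gs = grid_search(matrix, strong_data.labels, "RF", small_grid,
                         CVPlan(folds=3, repeats=1, seed=0))
        assert gs.mean_auc >= 0.95

    def test_label_permuted_auc_near_half(self, null_data, small_grid):
        matrix = encode_dataset(null_data, "dpc")
        rng = np.random.default_rng(3)
        labels = rng.permutation(np.asarray(null_data.labels))
        gs = grid_search(matrix, labels, "RF",
                         {"ntree": (100,), "mtry": (1,), "nsplit": (2,)},
                         CVPlan(folds=5, repeats=1, seed=3))
        assert 0.4 <= gs.mean_auc <= 0.6

    def test_oof_covers_every_record(self, strong_data, small_grid):
        matrix = encode_dataset(strong_data, "aac")
        gs = grid_search(matrix, strong_data.labels, "RF", small_grid,
                         CVPlan(folds=4, repeats=2, seed=0))
        for oof in gs.per_repeat_oof:
            assert oof.shape == (len(strong_data),)
            assert np.all((oof >= 0) & (oof <= 1))


class TestConsensusParams:
    def test_identical_repeats_identity(self):
        p = HyperParams("RF", ntree=430, mtry=1, nsplit=2)
        assert consensus_params([p, p, p]) == p

    def test_odd_count_median(self):
        reps = [HyperParams("RF", ntree=t, mtry=1, nsplit=2)
                for t in (430, 410, 450)]
        assert consensus_params(reps).ntree == 430

    def test_even_count_median_snaps_to_grid(self):
        reps = [HyperParams("RF", ntree=t, mtry=1, nsplit=2)
                for t in (410, 450)]
        grid = {"ntree": tuple(range(50, 1000, 20)) + (1000,),
                "mtry": (1,), "nsplit": (2,)}
        assert consensus_params(reps, grid).ntree == 430

    def test_grid_snap_ties_toward_smaller(self):
        reps = [HyperParams("KNN", k=k) for k in (5, 7)]
        # median 6 is equidistant from grid points 5 and 7 -> snap to 5
        assert consensus_params(reps, {"k": (5, 7)}).k == 5

    def test_mixed_algorithms_rejected(self):
        with pytest.raises(ParameterError, match="mixed"):
            consensus_params([HyperParams("RF", ntree=50, mtry=1, nsplit=2),
                              HyperParams("KNN", k=3)])


class TestTuneCutoff:
    def test_separable_scores_tie_to_half(self):
        scores = np.array([0.95, 0.92, 0.9, 0.1, 0.08, 0.05])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert tune_cutoff(scores, labels) == pytest.approx(0.5)

    def test_single_pair_tie_rule(self):
        assert tune_cutoff([0.8, 0.2], [1, 0]) == pytest.approx(0.5)

    def test_imbalanced_overlap_matches_bruteforce(self):
        # minority positives with overlapping scores: brute-force the MCC
        # over the same grid and require agreement plus a sub-0.5 optimum
        rng = np.random.default_rng(5)
        pos = np.clip(rng.normal(0.45, 0.15, 40), 0, 1)
        neg = np.clip(rng.normal(0.25, 0.15, 60), 0, 1)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 40 + [0] * 60)
        best = None
        for i in range(99):
            c = 0.01 + i * 0.01
            _, _, _, mcc = threshold_metrics(
                confusion(labels, (scores >= c).astype(int)))
            key = (-mcc, abs(c - 0.5), c)
            if best is None or key < best[0]:
                best = (key, c)
        expected = best[1]
        assert tune_cutoff(scores, labels) == pytest.approx(expected)
        assert expected < 0.5

    def test_identical_scores_warn_and_return_half(self):
        with pytest.warns(UserWarning, match="identical"):
            assert tune_cutoff([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_scores_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            tune_cutoff([1.2, 0.1], [1, 0])


class TestEstimators:
    def test_ert_uses_full_sample_rf_bootstraps(self):
        rf = build_estimator(HyperParams("RF", ntree=50, mtry=1, nsplit=2), 0)
        ert = build_estimator(HyperParams("ERT", ntree=50, mtry=1, nsplit=2), 0)
        assert rf.bootstrap is True
        assert ert.bootstrap is False

    def test_svm_requires_probability(self):
        p = HyperParams("SVM", cost=1.0, gamma=0.1)
        with pytest.raises(ConfigurationError, match="probability"):
            build_estimator(p, 0, probability=False)
        assert build_estimator(p, 0).probability is True

    def test_knn_probability_is_neighbor_fraction(self, strong_data):
        matrix = encode_dataset(strong_data, "aac")
        est = build_estimator(HyperParams("KNN", k=5), 0)
        est.fit(matrix.values, strong_data.labels)
        probs = est.predict_proba(matrix.values)
        np.testing.assert_allclose(probs * 5, np.round(probs * 5), atol=1e-9)

    def test_irrelevant_field_rejected(self):
        with pytest.raises(ParameterError):
            HyperParams("KNN", k=3, ntree=100)
        with pytest.raises(ParameterError, match="requires"):
            HyperParams("RF", ntree=100, mtry=1)


class TestBundleAndPredict:
    @pytest.fixture(scope="class")
    def bundle(self, strong_data):
        matrix = encode_dataset(strong_data, "dpc")
        fset = FeatureSet(0.0, feature_names=list(matrix.feature_names))
        params = HyperParams("RF", ntree=80, mtry=2, nsplit=2)
        return train_final(matrix, strong_data.labels, params, fset,
                           seed=0, encoder="dpc")

    def test_save_load_identical_predictions(self, bundle, tmp_path, strong_data):
        path = tmp_path / "model.bundle"
        bundle.save(path)
        reloaded = ModelBundle.load(path)
        a = predict(bundle, strong_data)
        b = predict(reloaded, strong_data)
        np.testing.assert_array_equal(a["probability"], b["probability"])
        assert list(a["class"]) == list(b["class"])

    def test_boundary_probability_called_positive(self, bundle, strong_data):
        table = predict(bundle, strong_data)
        p0 = float(table["probability"].iloc[0])
        assert 0.0 < p0 < 1.0
        # a cutoff exactly at the record's probability -> positive (>=)
        import dataclasses
        at = dataclasses.replace(bundle, probability_cutoff=p0)
        just_above = dataclasses.replace(
            bundle, probability_cutoff=min(p0 + 1e-9, 1 - 1e-12))
        assert predict(at, strong_data)["class"].iloc[0] == 1
        assert predict(just_above, strong_data)["class"].iloc[0] == 0

    def test_training_batch_recalled(self, bundle, strong_data):
        table = predict(bundle, strong_data)
        acc = np.mean(table["class"].to_numpy(int)
                      == np.asarray(strong_data.labels))
        assert acc >= 0.99

    def test_encoder_version_guard(self, bundle, strong_data):
        import dataclasses
        stale = dataclasses.replace(bundle, encoder_version="0.0")
        with pytest.raises(ConfigurationError, match="encoder version"):
            predict(stale, strong_data)

    def test_cutoff_range_enforced(self, bundle):
        import dataclasses
        with pytest.raises(ParameterError):
            dataclasses.replace(bundle, probability_cutoff=1.0)


class TestSplitUtility:
    def test_stratified_split_sizes(self, strong_data):
        train, test = train_test_split_dataset(strong_data, 0.2, seed=0)
        assert len(train) + len(test) == len(strong_data)
        assert test.positives_count == 12 and test.negatives_count == 12

    def test_disjoint_and_deterministic(self, strong_data):
        t1 = train_test_split_dataset(strong_data, 0.25, seed=9)
        t2 = train_test_split_dataset(strong_data, 0.25, seed=9)
        assert t1[1].ids == t2[1].ids
        assert not set(t1[0].ids) & set(t1[1].ids)


class TestRunPipeline:
    @pytest.fixture(scope="class")
    def tiny_config(self):
        return PipelineConfig(
            fis_trees=200, fis_mtry=(1, 10), fis_folds=3,
            sweep_low=0.001, sweep_high=0.003, sweep_step=0.001,
            sweep_floor=0.0005,
            grid={"ntree": (50,), "mtry": (1, 2), "nsplit": (2,)},
            folds=3, repeats=2, seed=5,
        )

    @pytest.fixture(scope="class")
    def fitted(self, strong_data, tiny_config):
        return run_pipeline(strong_data, tiny_config)

    def test_selected_set_is_best(self, fitted):
        report = fitted.sweep_report
        best_auc = report.loc[
            report["cutoff"] == fitted.selected.cutoff, "mean_auc"].iloc[0]
        assert (best_auc >= report["mean_auc"] - 0.01).all()

    def test_deterministic_rerun(self, strong_data, tiny_config, fitted):
        again = run_pipeline(strong_data, tiny_config)
        assert again.selected.feature_names == fitted.selected.feature_names
        assert again.bundle.probability_cutoff == fitted.bundle.probability_cutoff
        np.testing.assert_array_equal(
            again.oof_probabilities, fitted.oof_probabilities)

    def test_report_columns(self, fitted):
        assert list(fitted.sweep_report.columns) == [
            "cutoff", "n_features", "mean_auc", "sd_auc"]

    def test_unlabeled_dataset_fails_at_encode_stage(self, strong_data,
                                                     tiny_config):
        from aippred.seqio import PeptideDataset, PeptideRecord
        unlabeled = PeptideDataset(
            [PeptideRecord(r.id, r.sequence, None) for r in strong_data])
        with pytest.raises(PipelineError, match="encode"):
            run_pipeline(unlabeled, tiny_config)
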