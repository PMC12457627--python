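import json

import numpy as np
import pytest

import hsibench as hb
from hsibench.training_harness import EarlyStopper, _permuted_entries


class TestCVPlan:
    def test_56_patients_give_56_folds_of_expected_shape(self):
        ids = [f"pat{i:02d}" for i in range(56)]
        plan = hb.make_cv_plan(ids, n_val=3, mapping_seed=0)
        assert len(plan.folds) == 56
        for fold in plan.folds:
            assert len(fold.validation_patients) == 3
            assert len(fold.train_patients) == 52
            union = {fold.test_patient, *fold.validation_patients, *fold.train_patients}
            assert union == set(ids)
        assert sorted(plan.patient_ids()) == ids

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            hb.make_cv_plan(["a", "b", "c", "d"], n_val=3)

    def test_plan_serialization_byte_identical(self, tmp_path):
        ids = [f"p{i}" for i in range(8)]
        for i in range(2):
            hb.make_cv_plan(ids, mapping_seed=9).save(tmp_path / f"plan{i}.json")
        assert (tmp_path / "plan0.json").read_bytes() == (tmp_path / "plan1.json").read_bytes()
        back = hb.CVPlan.load(tmp_path / "plan0.json")
        assert back == hb.make_cv_plan(ids, mapping_seed=9)

    def test_validation_mapping_depends_only_on_seed_and_test_id(self):
        # adding an unrelated patient must not change X's validation set
        # except where the new id itself is drawn
        a = hb.make_cv_plan([f"p{i}" for i in range(8)], mapping_seed=4)
        b = hb.make_cv_plan([f"p{i}" for i in range(8)], mapping_seed=5)
        assert any(
            fa.validation_patients != fb.validation_patients
            for fa, fb in zip(a.folds, b.folds)
        )


class TestModel:
    def test_identical_seeds_give_identical_initial_parameters(self):
        spec = hb.ModelSpec(patch_size=3, n_bands=20)
        m1 = hb.build_model(spec, init_seed=1)
        m2 = hb.build_model(spec, init_seed=1)
        assert m1.param_checksum() == m2.param_checksum()
        m3 = hb.build_model(spec, init_seed=2)
        assert m3.param_checksum() != m1.param_checksum()

    def test_output_is_a_single_probability(self, rng):
        spec = hb.ModelSpec(patch_size=3, n_bands=92)
        model = hb.build_model(spec)
        X = rng.normal(size=(7, 3, 3, 92)).astype(np.float32)
        prob = model.predict(X)
        assert prob.shape == (7,)
        assert np.all((prob > 0) & (prob < 1))

    def test_inference_is_deterministic(self):
        spec = hb.ModelSpec(patch_size=3, n_bands=10)
        model = hb.build_model(spec)
        X = np.zeros((3, 3, 3, 10), dtype=np.float32)
        np.testing.assert_array_equal(model.predict(X), model.predict(X))

    def test_gradients_match_finite_differences(self):
        spec = hb.ModelSpec(patch_size=3, n_bands=5, b1_filters=2, b2_reduce=2,
                            b2_filters=2, b3_filters=2, dense_units=4, dropout_rate=0.0)
        model = hb.build_model(spec, init_seed=1)
        for k in model.params:
            model.params[k] = model.params[k].astype(np.float64)
        rng = np.random.default_rng(0)
        X = rng.random((4, 3, 3, 5))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([2.0, 1.0, 1.0, 1.0])

        def loss():
            p, _ = model.forward(X)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / w.sum())

        prob, cache = model.forward(X)
        grads = model._backward(prob, y, w, cache)
        eps = 1e-6
        for key in ("c2_W", "c2r_W", "c1_W", "c3_W", "d1_W", "out_W", "c2_b"):
            P = model.params[key]
            flat_idx = int(np.argmax(np.abs(np.asarray(grads[key]))))
            idx = np.unravel_index(flat_idx, P.shape)
            P[idx] += eps
            lp = loss()
            P[idx] -= 2 * eps
            lm = loss()
            P[idx] += eps
            numeric = (lp - lm) / (2 * eps)
            assert np.asarray(grads[key])[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestEarlyStopping:
    def test_stops_after_patience_exceeded_on_flat_score(self):
        stopper = EarlyStopper(patience=5)
        outcomes = [stopper.update(0.4) for _ in range(10)]
        # first epoch sets the best; stop once 6 epochs pass without improvement
        assert outcomes.index(True) == 6
        assert stopper.best_epoch == 1

    def test_improvement_resets_the_counter(self):
        stopper = EarlyStopper(patience=2)
        schedule = [0.1, 0.2, 0.2, 0.3, 0.3, 0.3, 0.3]
        outcomes = [stopper.update(s) for s in schedule]
        assert outcomes == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 4

    def test_training_never_exceeds_max_epochs(self, small_cohort, small_subset):
        combo = hb.PreprocessingCombination()
        plan = hb.make_cv_plan([r.patient_id for r in small_cohort], mapping_seed=0)
        cfg = hb.desk_scale_config(max_epochs=3, eval_max_pixels=60)
        res = hb.train_combination(small_cohort, small_subset, combo, plan, cfg)
        assert all(f["epochs_run"] <= 3 for f in res.manifest["folds"])

    def test_f1_at_threshold_counts(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        assert hb.f1_at_threshold(labels, scores) == pytest.approx(0.5)
        assert hb.f1_at_threshold(np.array([0, 0]), np.array([0.1, 0.2])) == 0.0


@pytest.fixture(scope="module")
def tiny_run(small_cohort, small_subset):
    combo = hb.PreprocessingCombination(scaling="standardization", weighting="sample")
    plan = hb.make_cv_plan([r.patient_id for r in small_cohort], mapping_seed=1)
    cfg = hb.desk_scale_config(max_epochs=2, eval_max_pixels=80)
    res = hb.train_combination(small_cohort, small_subset, combo, plan, cfg)
    return combo, plan, cfg, res


class TestTrainCombination:
    def test_rerun_is_bit_identical(self, small_cohort, small_subset, tiny_run):
        combo, plan, cfg, res = tiny_run
        res2 = hb.train_combination(small_cohort, small_subset, combo, plan, cfg)
        assert json.dumps(res.manifest, sort_keys=True) == json.dumps(
            res2.manifest, sort_keys=True
        )
        for pid in res.patient_scores:
            np.testing.assert_array_equal(
                res.patient_scores[pid]["scores"], res2.patient_scores[pid]["scores"]
            )

    def test_manifest_records_seeds_stages_and_epochs(self, tiny_run):
        _, _, cfg, res = tiny_run
        m = res.manifest
        assert m["seeds"] == {
            "init_seed": cfg.init_seed,
            "shuffle_seed": cfg.shuffle_seed,
            "dropout_seed": cfg.dropout_seed,
            "mapping_seed": 1,
        }
        assert m["pipeline_stages"][0] == "artifact_metrics"
        assert all("epochs_run" in f and "score_checksum" in f for f in m["folds"])

    def test_sample_order_identical_across_combinations(
        self, small_cohort, small_subset, tiny_run
    ):
        """The central confound control: two different preprocessing
        combinations deliver the same training pixels in the same order."""
        _, plan, cfg, res = tiny_run
        other = hb.PreprocessingCombination(
            scaling="normalization",
            smoothing=hb.SmoothingSpec("d1", "median", 3),
            weighting="class",
        )
        res2 = hb.train_combination(small_cohort, small_subset, other, plan, cfg)
        assert res.fold_train_order == res2.fold_train_order

    def test_filtering_preserves_relative_order_of_survivors(
        self, small_cohort, small_subset, tiny_run, spectral_model
    ):
        combo, plan, cfg, res = tiny_run
        thr = hb.true_blood_threshold(spectral_model, small_cohort[0].cube.grid)
        filtered_combo = hb.PreprocessingCombination(
            filtering=hb.FilterSpec(blood_threshold=thr)
        )
        res2 = hb.train_combination(small_cohort, small_subset, filtered_combo, plan, cfg)
        for pid in res.fold_train_order:
            full = res.fold_train_order[pid]
            kept = res2.fold_train_order[pid]
            positions = [full.index(e) for e in kept]
            assert positions == sorted(positions)

    def test_permutation_is_shared_and_seeded(self, small_subset):
        a = _permuted_entries(small_subset, 2)
        b = _permuted_entries(small_subset, 2)
        c = _permuted_entries(small_subset, 3)
        assert a == b
        assert a != c
        assert sorted(a) == sorted(small_subset.entries)

    def test_scores_lie_in_unit_interval(self, tiny_run):
        _, _, _, res = tiny_run
        for data in res.patient_scores.values():
            assert np.all((data["scores"] > 0) & (data["scores"] < 1))
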