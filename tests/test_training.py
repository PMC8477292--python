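import numpy as np
import pytest

from hvec.model import HVecParams
from hvec.synthetic_cohort import GeneratorConfig, generate_cohort
from hvec.training import (
    GradientBundle,
    TrainingConfig,
    combine_gradients,
    split_cohort,
    train,
    upsample_batch,
    weighted_task_loss,
)


def combine_oracle(G, V_list):
    """Independent direct evaluation of the cosine-gated combination."""
    out = G.astype(float).copy()
    for V in V_list:
        denom = np.sqrt((G * G).sum()) * np.sqrt((V * V).sum())
        cos = (G * V).sum() / denom if denom > 0 else 0.0
        out = out + max(0.0, cos) * V
    return out


class TestCombineGradients:
    def test_orthogonal_auxiliary_is_fully_gated_out(self):
        G = np.array([1.0, 0.0])
        V = np.array([0.0, 5.0])
        np.testing.assert_array_equal(combine_gradients(G, [V]), G)

    def test_anti_aligned_auxiliary_is_fully_gated_out(self):
        G = np.array([1.0, 2.0, -1.0])
        np.testing.assert_array_equal(combine_gradients(G, [-3.0 * G]), G)

    def test_aligned_auxiliary_doubles_the_direction(self):
        G = np.array([0.5, -1.5, 2.0])
        np.testing.assert_allclose(combine_gradients(G, [G]), 2.0 * G)

    def test_empty_auxiliary_list_returns_g(self):
        G = np.array([1.0, 2.0])
        np.testing.assert_array_equal(combine_gradients(G, []), G)

    def test_zero_vectors_define_cosine_as_zero(self):
        G = np.zeros(3)
        V = np.ones(3)
        np.testing.assert_array_equal(combine_gradients(G, [V]), G)
        np.testing.assert_array_equal(combine_gradients(V, [G]), V)

    def test_matches_direct_formula_on_random_bundles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            G = rng.normal(size=40)
            V_list = [rng.normal(size=40) for _ in range(rng.integers(0, 5))]
            got = combine_gradients(G, V_list)
            exp = combine_oracle(G, V_list)
            np.testing.assert_allclose(got, exp, rtol=1e-12, atol=1e-12)

    def test_conflicting_gradient_removal_equivalence(self):
        # a negative-cosine auxiliary contributes nothing at all
        rng = np.random.default_rng(1)
        G = rng.normal(size=30)
        V_pos = rng.normal(size=30) + 0.5 * G
        V_neg = -G + 0.01 * rng.normal(size=30)
        assert (G @ V_neg) < 0
        np.testing.assert_array_equal(
            combine_gradients(G, [V_pos, V_neg]), combine_gradients(G, [V_pos]))

    def test_bundle_interface_and_length_validation(self):
        G = np.ones(4)
        bundle = GradientBundle(G=G, V_list=[np.ones(4)], alpha=0.1)
        np.testing.assert_allclose(combine_gradients(bundle), 2 * np.ones(4))
        with pytest.raises(ValueError):
            combine_gradients(G, [np.ones(3)])


class TestWeightedLoss:
    def test_uniform_weights_reduce_to_mean(self):
        losses = [0.2, 0.4, 0.9]
        got = weighted_task_loss(losses, [0, 1, 0], [0, 1, 0], 1.0, 1.0)
        assert got == pytest.approx(np.mean(losses))

    def test_all_ca_batch_normalization_cancels(self):
        losses = [0.2, 0.4, 0.9]
        got = weighted_task_loss(losses, [0, 1, 1], [1, 1, 1], 5.0, 1.0)
        assert got == pytest.approx(np.mean(losses))

    def test_mixed_batch_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        losses = rng.random(20)
        is_ca = rng.integers(0, 2, 20)
        w_pos, w_neg = 5.0, 1.0
        w = np.where(is_ca == 1, w_pos, w_neg)
        expected = (w * losses).sum() / w.sum()
        got = weighted_task_loss(losses, np.zeros(20), is_ca, w_pos, w_neg)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_task_loss([], [], [], 1.0, 1.0)


class TestUpsampling:
    def _persons(self, cohort, n):
        return cohort.persons[:n]

    def test_rate_one_is_a_permutation(self, small_cohort):
        persons = self._persons(small_cohort, 20)
        out = upsample_batch(persons, {persons[0].person_id}, rate=1, seed=3)
        assert sorted(p.person_id for p in out) == \
            sorted(p.person_id for p in persons)

    def test_positive_person_replicated_rate_times(self, small_cohort):
        persons = self._persons(small_cohort, 15)
        pos = persons[4].person_id
        out = upsample_batch(persons, {pos}, rate=10, seed=0)
        assert sum(1 for p in out if p.person_id == pos) == 10

    def test_batch_size_counting(self, small_cohort):
        persons = self._persons(small_cohort, 30)
        positives = {p.person_id for p in persons[:4]}
        rate = 7
        out = upsample_batch(persons, positives, rate, seed=1)
        assert len(out) == (len(persons) - len(positives)) + rate * len(positives)

    def test_invalid_rate_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            upsample_batch(self._persons(small_cohort, 3), set(), rate=0, seed=0)


class TestSplit:
    def test_hundred_persons_split_70_15_15(self):
        cohort = generate_cohort(GeneratorConfig(n_persons=100, seed=5))
        tr, va, te = split_cohort(cohort, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_partition_properties(self, small_cohort):
        tr, va, te = split_cohort(small_cohort, seed=1)
        ids = [p.person_id for part in (tr, va, te) for p in part]
        assert len(ids) == len(set(ids)) == len(small_cohort.persons)

    def test_no_person_straddles_splits(self, small_cohort):
        tr, va, te = split_cohort(small_cohort, seed=2)
        by_split = [ {p.person_id for p in part} for part in (tr, va, te) ]
        for rid_owner in by_split:
            for other in by_split:
                if rid_owner is not other:
                    assert not (rid_owner & other)
        # record-level check: each record's person sits in exactly one split
        for person in small_cohort.persons:
            hits = sum(person.person_id in s for s in by_split)
            assert hits == 1

    def test_tiny_cohort_rejected(self):
        cohort = generate_cohort(GeneratorConfig(n_persons=2, seed=0))
        with pytest.raises(ValueError):
            split_cohort(cohort, seed=0)

    def test_bad_fractions_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_cohort(small_cohort, fractions=(0.5, 0.2, 0.2), seed=0)


@pytest.fixture(scope="module")
def trained_pair(medium_cohort):
    """One short multitask training run on a 2,000-person cohort."""
    params = HVecParams(init_seed=0)
    config = TrainingConfig(multitask=True, max_epochs=2, seed=4)
    trained, history = train(medium_cohort, params, config)
    return trained, history


class TestTraining:
    def test_single_task_mode_passes_empty_auxiliary_list(self, small_cohort,
                                                          monkeypatch):
        import hvec.training as tr
        calls = []
        orig = tr.combine_gradients

        def spy(G, V_list=None):
            calls.append(0 if V_list is None else len(V_list))
            return orig(G, V_list)

        monkeypatch.setattr(tr, "combine_gradients", spy)
        config = TrainingConfig(multitask=False, max_epochs=1, seed=0)
        tr.train(small_cohort, HVecParams(), config)
        assert calls and all(c == 0 for c in calls)

    def test_multitask_passes_six_auxiliary_gradients(self, small_cohort,
                                                      monkeypatch):
        import hvec.training as tr
        calls = []
        orig = tr.combine_gradients

        def spy(G, V_list=None):
            calls.append(len(V_list))
            return orig(G, V_list)

        monkeypatch.setattr(tr, "combine_gradients", spy)
        config = TrainingConfig(multitask=True, max_epochs=1, seed=0)
        tr.train(small_cohort, HVecParams(), config)
        assert calls and all(c == 6 for c in calls)

    def test_fixed_seed_training_is_bitwise_reproducible(self, small_cohort):
        params = HVecParams(init_seed=1)
        config = TrainingConfig(multitask=True, max_epochs=2, seed=9)
        t1, h1 = train(small_cohort, params, config)
        t2, h2 = train(small_cohort, params, config)
        np.testing.assert_array_equal(t1.model.param_vector(),
                                      t2.model.param_vector())
        assert h1 == h2

    def test_validation_and_test_sets_contain_no_duplicates(self, trained_pair):
        trained, _ = trained_pair
        for split in ("val", "test"):
            ids = trained.split_ids[split]
            assert len(ids) == len(set(ids))
        assert not (set(trained.split_ids["val"]) & set(trained.split_ids["test"]))
        assert not (set(trained.split_ids["train"]) & set(trained.split_ids["test"]))

    def test_history_records_all_task_losses(self, trained_pair):
        _, history = trained_pair
        assert len(history) == 2
        for row in history:
            assert {"loss_mortality", "loss_recon_codes", "loss_ihca",
                    "val_auroc_main"} <= set(row)

    def test_scaler_is_frozen_after_training(self, trained_pair):
        trained, _ = trained_pair
        assert trained.scaler.fitted
        with pytest.raises(RuntimeError):
            trained.scaler.fit(np.zeros((2, 707)))

    def test_checkpoint_round_trip_preserves_predictions(self, small_cohort,
                                                         tmp_path):
        from hvec.training import TrainedModel
        config = TrainingConfig(multitask=False, max_epochs=1, seed=5)
        trained, _ = train(small_cohort, HVecParams(), config)
        path = str(tmp_path / "model.npz")
        trained.save(path)
        loaded = TrainedModel.load(path, small_cohort)
        persons = {p.person_id: p for p in small_cohort.persons}
        test_p = [persons[i] for i in trained.split_ids["test"]]
        ids1, s1, l1, c1 = trained.predict_scores(test_p)
        ids2, s2, l2, c2 = loaded.predict_scores(test_p)
        assert ids1 == ids2
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(l1, l2)

    def test_readmission_main_task_trains(self, small_cohort):
        config = TrainingConfig(multitask=False, max_epochs=1, seed=0,
                                main_task="readmission")
        trained, history = train(small_cohort, HVecParams(), config)
        assert "loss_readmission" in history[0]


class TestDescentSanity:
    def test_gated_updates_descend_on_a_convex_problem(self):
        # logistic regression as the main task, a random quadratic as the
        # auxiliary: cosine-gated steps must not increase the main loss
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 10))
        w_true = rng.normal(size=10)
        y = (X @ w_true + 0.1 * rng.normal(size=200) > 0).astype(float)
        w = np.zeros(10)
        aux_target = rng.normal(size=10)

        def main_loss_grad(w):
            z = X @ w
            p = 1 / (1 + np.exp(-z))
            loss = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * y)
            return loss, X.T @ (p - y) / len(y)

        losses = []
        for _ in range(60):
            loss, G = main_loss_grad(w)
            V = w - aux_target  # gradient of 0.5||w - aux_target||^2
            w = w - 0.1 * combine_gradients(G, [V])
            losses.append(loss)
        assert losses[-1] < losses[0]
        increases = np.diff(losses)
        assert np.all(increases < 1e-3)
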