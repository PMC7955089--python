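"""Rewards, policy-gradient updates, discriminator losses, augmentation."""

import copy

import numpy as np
import pytest

import mutgan as mg
from mutgan import nn
from mutgan.adversarial import _clean_component


def _fitted_discriminators(dataset, seed=0, epochs=1):
    X, lengths, y = dataset.to_arrays()
    ex = mg.MutationExplainer(alphabet=dataset.alphabet,
                              random_state=seed).initialize()
    clf = mg.SequenceClassifier(alphabet=dataset.alphabet, epochs=epochs,
                                random_state=seed)
    clf.fit(X, y, lengths=lengths)
    return ex, clf


class TestReward:
    def test_reward_extremes(self):
        # undetected and classified clean -> Q = 1; fully detected and
        # classified modified -> Q = -1
        assert mg.RewardSignal(0.0, 1.0).Q == 1.0
        assert mg.RewardSignal(1.0, 0.0).Q == -1.0

    def test_reward_arithmetic(self):
        sig = mg.RewardSignal(explain_component=0.3, classify_component=0.8)
        assert sig.Q == pytest.approx(0.5)
        assert sig.R_T == sig.Q

    def test_empty_mask_has_zero_explain_component(self, donor_dataset):
        ex, clf = _fitted_discriminators(donor_dataset)
        X, lengths, y = donor_dataset.to_arrays()
        rewards = mg.sequence_reward(
            X[:4], np.zeros_like(X[:4]), lengths[:4], ex, clf,
            labeling="gene_merge", source_labels=y[:4])
        assert all(r.explain_component == 0.0 for r in rewards)

    def test_q_always_bounded(self, donor_dataset):
        ex, clf = _fitted_discriminators(donor_dataset)
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=3).fit()
        X, lengths, y = donor_dataset.to_arrays()
        batch = mut.sample(X, lengths, n_replace=3,
                           rng=np.random.default_rng(0))
        rewards = mg.sequence_reward(batch.filled_X, batch.masks, lengths,
                                     ex, clf, labeling="gene_merge",
                                     source_labels=y)
        qs = np.asarray([r.Q for r in rewards])
        assert np.all((qs >= -1.0) & (qs <= 1.0))
        for r in rewards:
            assert r.Q == pytest.approx(r.classify_component
                                        - r.explain_component)

    def test_clean_component_labeling_rules(self):
        probs = np.asarray([[0.1, 0.2, 0.3, 0.4]])
        classes = np.asarray(["DN", "DN'", "DP", "DP'"], dtype=object)
        primed = _clean_component(probs, classes, "primed", None, None)
        assert primed[0] == pytest.approx(0.1 + 0.3)
        merged = _clean_component(probs, classes, "gene_merge", ["DP"], None)
        assert merged[0] == pytest.approx(0.3)
        two = _clean_component(np.asarray([[0.7, 0.3]]),
                               np.asarray(["N", "R"], dtype=object),
                               "two_class", None, "N")
        assert two[0] == pytest.approx(0.7)


class TestDiscriminatorLoss:
    def test_uniform_half_predictions_give_ln2_per_term(self, donor_dataset):
        # closed form: BCE at p = 0.5 is ln 2 regardless of the target
        ex, clf = _fitted_discriminators(donor_dataset)
        for p in ex.net_.parameters():
            p.data[...] = 0.0  # sigmoid(0) = 0.5 everywhere
        for p in clf.net_.parameters():
            p.data[...] = 0.0
        X, lengths, y = donor_dataset.to_arrays()
        masks = np.zeros_like(X)
        masks[:, :3] = 1
        loss_e = mg.discriminator_loss(X, masks, y, lengths, ex, clf,
                                       lambda_explain=1.0,
                                       lambda_classify=0.0)
        assert float(loss_e.data) == pytest.approx(np.log(2), abs=1e-9)
        loss_c = mg.discriminator_loss(X, masks, y, lengths, ex, clf,
                                       lambda_explain=0.0,
                                       lambda_classify=1.0)
        assert float(loss_c.data) == pytest.approx(np.log(2), abs=1e-9)

    def test_zero_explain_weight_collapses_to_classify_term(self,
                                                            donor_dataset):
        ex, clf = _fitted_discriminators(donor_dataset)
        X, lengths, y = donor_dataset.to_arrays()
        masks = np.zeros_like(X)
        lc = 0.37
        full = mg.discriminator_loss(X, masks, y, lengths, ex, clf,
                                     lambda_explain=0.0, lambda_classify=lc)
        codes = clf._encode_labels(y)
        alone = clf.loss(X, codes, lengths)
        assert float(full.data) == pytest.approx(lc * float(alone.data))

    def test_perfect_predictions_drive_loss_to_zero(self, donor_dataset):
        ex, clf = _fitted_discriminators(donor_dataset)
        X, lengths, y = donor_dataset.to_arrays()
        masks = np.zeros_like(X)
        for p in ex.net_.parameters():
            p.data[...] = 0.0
        ex.net_.out.b.data[...] = -40.0  # probability ~0 == the mask
        loss = mg.discriminator_loss(X, masks, y, lengths, ex, clf,
                                     lambda_explain=1.0, lambda_classify=0.0)
        assert float(loss.data) < 1e-6

    def test_both_weights_zero_rejected(self, donor_dataset):
        ex, clf = _fitted_discriminators(donor_dataset)
        X, lengths, y = donor_dataset.to_arrays()
        with pytest.raises(ValueError):
            mg.discriminator_loss(X, np.zeros_like(X), y, lengths, ex, clf,
                                  lambda_explain=0.0, lambda_classify=0.0)


class TestReinforce:
    def test_centered_rewards_give_zero_update(self, tiny_mutator):
        mut = tiny_mutator
        X = np.tile([2, 3, 4, 2], (6, 1))
        lengths = np.full(6, 4)
        batch = mut.sample(X, lengths, n_replace=1,
                           rng=np.random.default_rng(0), want_logp=True)
        opt = nn.Adam(mut.selector_.parameters(), lr=1e-3)
        before = [p.data.copy() for p in mut.selector_.parameters()]
        mg.reinforce_update(batch, np.zeros(6), opt, "where", baseline=0.0)
        after = [p.data for p in mut.selector_.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_empty_batch_is_noop(self, tiny_mutator):
        batch = tiny_mutator.sample(np.zeros((0, 4), dtype=np.int64),
                                    np.zeros(0, dtype=np.int64),
                                    n_replace=1, want_logp=True,
                                    rng=np.random.default_rng(0))
        opt = nn.Adam(tiny_mutator.selector_.parameters())
        assert mg.reinforce_update(batch, [], opt, "where") == 0.0

    def test_updates_climb_the_expected_reward(self):
        # hill-climb property: on a frozen reward landscape, repeated
        # policy-gradient updates must increase the enumeration-oracle
        # expected reward
        alphabet = mg.build_alphabet(("a", "b", "c"))
        mut = mg.SequenceMutator(
            alphabet=alphabet, embed_dim=8, where_hidden=(4, 4),
            where_dense=4, replace_hidden=(6, 6), attn_hidden=4,
            exclude_source=False, random_state=2).fit()
        X = np.asarray([[2, 3, 4, 2]])
        lengths = np.asarray([4])
        fills = mut.fill_ids_
        R = np.zeros((4, len(fills)))
        R[2, 0] = 1.0  # only (position 2, fill 'a') pays off

        def expected_reward():
            with nn.no_grad():
                p = mut.selector_.probabilities(X, lengths)[0]
            q = p + 1e-8
            piw = q / q.sum()
            J = 0.0
            for pos in range(4):
                masks = np.zeros((1, 4), dtype=np.int64)
                masks[0, pos] = 1
                for fi, v in enumerate(fills):
                    forced = X.copy()
                    forced[0, pos] = v
                    with nn.no_grad():
                        _, lp = mut.infiller_.fill(
                            X, masks, lengths, forced=forced,
                            exclude_source=False, fill_ids=fills,
                            want_logp=True)
                    J += piw[pos] * np.exp(lp.data[0]) * R[pos, fi]
            return float(J)

        opt_w = nn.Adam(mut.selector_.parameters(), lr=5e-3)
        opt_r = nn.Adam(mut.infiller_.parameters(), lr=5e-3)
        rng = np.random.default_rng(0)
        fill_col = {v: i for i, v in enumerate(fills)}
        Xb = np.repeat(X, 64, axis=0)
        lb = np.repeat(lengths, 64)
        j_start = expected_reward()
        checkpoints = [j_start]
        for step in range(30):
            batch = mut.sample(Xb, lb, n_replace=1, rng=rng,
                               mode="sample", want_logp=True)
            pos = batch.positions[:, 0]
            vals = batch.filled_X[np.arange(64), pos]
            r = R[pos, [fill_col[v] for v in vals]]
            mg.reinforce_update(batch, r, opt_w, "where", baseline=r.mean())
            mg.reinforce_update(batch, r, opt_r, "replace", baseline=r.mean())
            if step % 10 == 9:
                checkpoints.append(expected_reward())
        assert checkpoints[-1] > j_start + 0.1
        assert all(b >= a - 0.02 for a, b in zip(checkpoints, checkpoints[1:]))


class TestPretrain:
    def test_classifier_learns_the_motif(self):
        spec = mg.CompositionSpec(counts={"DP": 400, "DN": 400}, seed=6)
        ds = mg.generate_nn269_mimic(spec)
        cfg = mg.TrainConfig(seed=6)
        splits = mg.make_splits(ds.labels, "holdout", test_size=0.2, seed=0)
        train_idx, test_idx = splits[0]
        clf = mg.pretrain_classifier(ds.subset(train_idx), cfg)
        test = ds.subset(test_idx)
        X, lengths, y = test.to_arrays()
        acc = mg.accuracy(y, clf.predict(X, lengths))
        assert acc > 0.85

    def test_frozen_classifier_weights_stay_bit_identical(self,
                                                          donor_dataset):
        cfg = mg.TrainConfig(pretrain_epochs=1, seed=0)
        clf = mg.pretrain_classifier(donor_dataset, cfg)
        assert clf.frozen_
        before = {k: v.copy() for k, v in clf.net_.state_dict().items()}
        X, lengths, y = donor_dataset.to_arrays()
        clf.partial_fit(X, y, lengths=lengths, epochs=2)  # must be a no-op
        after = clf.net_.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_pretraining_deterministic_under_seed(self, donor_dataset):
        cfg = mg.TrainConfig(pretrain_epochs=1, seed=3)
        a = mg.pretrain_classifier(donor_dataset, cfg).net_.state_dict()
        b = mg.pretrain_classifier(donor_dataset, cfg).net_.state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_single_class_data_rejected(self, dna):
        seqs = mg.sample_sequences(mg.donor_motif(), 10, True, seed=0,
                                   label="DP")
        ds = mg.SequenceDataset(seqs, dna)
        # gene_merge keeps the single label, so augmentation cannot help
        with pytest.raises(ValueError, match="two classes"):
            mg.pretrain_classifier(ds, mg.TrainConfig(pretrain_epochs=1))


class TestAugmentation:
    def test_one_mutant_per_source_with_exact_budgets(self, acceptor_dataset,
                                                      donor_dataset):
        for ds, expect in ((acceptor_dataset, 9), (donor_dataset, 3)):
            mut = mg.SequenceMutator(alphabet=ds.alphabet,
                                     random_state=0).fit()
            mutants = mg.augment_dataset(ds, mut, labeling="gene_merge",
                                         seed=1)
            assert len(mutants) == len(ds)
            for src, m in zip(ds, mutants):
                diff = np.flatnonzero(src.token_ids != m.token_ids)
                assert diff.size == expect
                assert np.array_equal(np.flatnonzero(m.truth_mask), diff)
                assert m.source_id == src.id

    def test_labeling_rules(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=0).fit()
        primed = mg.augment_dataset(donor_dataset, mut, labeling="primed",
                                    seed=1)
        assert {m.label for m in primed} == {"DP'", "DN'"}
        assert mg.primed_label("AP") == "AP'"
        merged = mg.augment_dataset(donor_dataset, mut,
                                    labeling="gene_merge", seed=1)
        assert {m.label for m in merged} == {"DP", "DN"}
        two = mg.augment_dataset(donor_dataset, mut, labeling="two_class",
                                 generated_label="R", seed=1)
        assert {m.label for m in two} == {"R"}

    def test_unknown_labeling_rejected(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet).fit()
        with pytest.raises(ValueError, match="labeling"):
            mg.augment_dataset(donor_dataset, mut, labeling="bogus")

    def test_sampling_mode_avoids_mask_collapse(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=0).fit()
        one = mg.SequenceDataset([donor_dataset[0]] * 100,
                                 donor_dataset.alphabet)
        mutants = mg.augment_dataset(one, mut, labeling="gene_merge", seed=2)
        distinct = {tuple(m.truth_mask) for m in mutants}
        assert len(distinct) >= 2


@pytest.fixture(scope="module")
def small_fit():
    spec = mg.CompositionSpec(counts={"DP": 40, "DN": 40}, seed=2)
    ds = mg.generate_nn269_mimic(spec)
    cfg = mg.TrainConfig(epochs=2, pretrain_epochs=1, seed=2)
    aug = mg.AdversarialAugmenter(alphabet=ds.alphabet, config=cfg)
    return ds, cfg, aug.fit(ds)


class TestTrainingLoop:
    def test_history_records_every_epoch(self, small_fit):
        _, cfg, aug = small_fit
        assert len(aug.history_) == cfg.epochs
        for rec in aug.history_:
            assert {"epoch", "n_replace_frac", "mean_Q", "g_loss", "d_loss",
                    "val_explain_macro_f1"} <= set(rec)
            assert -1.0 <= rec["mean_Q"] <= 1.0

    def test_schedule_anneals_downwards(self, small_fit):
        _, _, aug = small_fit
        fracs = [rec["n_replace_frac"] for rec in aug.history_]
        assert fracs[0] == pytest.approx(0.5)
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))

    def test_training_is_deterministic_under_master_seed(self, small_fit):
        ds, cfg, aug = small_fit
        rerun = mg.AdversarialAugmenter(alphabet=ds.alphabet,
                                        config=cfg).fit(ds)
        assert rerun.history_ == aug.history_

    def test_zero_generator_steps_leave_generators_untouched(self):
        spec = mg.CompositionSpec(counts={"DP": 30, "DN": 30}, seed=4)
        ds = mg.generate_nn269_mimic(spec)
        cfg = mg.TrainConfig(epochs=1, pretrain_epochs=1, g_step=0, seed=4)
        aug = mg.AdversarialAugmenter(alphabet=ds.alphabet, config=cfg)
        aug.fit(ds)
        fresh = mg.SequenceMutator(alphabet=ds.alphabet,
                                   random_state=cfg.seed + 21).fit()
        trained = aug.mutator_.selector_.state_dict()
        init = fresh.selector_.state_dict()
        assert all(np.array_equal(trained[k], init[k]) for k in init)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError, match="anneals downwards"):
            mg.TrainConfig(n_replace_start=0.1, n_replace_end=0.5)
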