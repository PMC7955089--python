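"""Position selection, binarisation, masking and blank infilling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mutgan as mg
from mutgan import nn


class TestSelectorContracts:
    def test_probabilities_in_unit_interval(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=1).fit()
        X, lengths, _ = donor_dataset.to_arrays()
        p = mut.selector_.probabilities(X[:8], lengths[:8])
        assert np.all((p >= 0) & (p <= 1))

    def test_padding_positions_forced_to_zero(self, dna):
        mut = mg.SequenceMutator(alphabet=dna, random_state=1).fit()
        X = np.zeros((2, 10), dtype=np.int64)
        X[0, :4] = [2, 3, 4, 5]
        p = mut.selector_.probabilities(X, np.asarray([4, 0]))
        assert np.all(p[0, 4:] == 0)
        assert np.all(p[1] == 0)

    def test_single_unit_network_matches_scalar_recomputation(self):
        # a hand-reduced network: all recurrent weights zeroed so each
        # position's score is a closed-form function of its embedding
        alphabet = mg.build_alphabet(("a", "b"))
        mut = mg.SequenceMutator(alphabet=alphabet, embed_dim=2,
                                 where_hidden=(1, 1), where_dense=1,
                                 random_state=3).fit()
        sel = mut.selector_
        for p in sel.parameters():
            p.data[...] = 0.0
        sel.out.b.data[...] = 0.7
        X = np.asarray([[2, 3, 2]])
        p = sel.probabilities(X, np.asarray([3]))
        # dense(0)->relu(0)=0, out = sigmoid(0.7) at every position
        expected = 1.0 / (1.0 + np.exp(-0.7))
        assert np.allclose(p, expected, atol=1e-12)


class TestBinarise:
    def test_deterministic_argmax(self):
        mask = mg.binarize_topk(np.asarray([0.9, 0.1, 0.2]), 1, 3)
        assert mask.tolist() == [1, 0, 0]

    def test_tie_breaks_to_lowest_index(self):
        mask = mg.binarize_topk(np.asarray([0.5, 0.5]), 1, 2)
        assert mask.tolist() == [1, 0]

    def test_acceptor_budget_is_nine(self):
        p = np.random.default_rng(0).random(90)
        mask = mg.binarize_topk(p, 9, 90)
        assert mask.sum() == 9

    def test_fraction_resolves_round_half_up(self):
        assert mg.resolve_n_replace(0.1, 15) == 2  # 1.5 rounds up
        assert mg.resolve_n_replace(0.1, 90) == 9
        assert mg.resolve_n_replace(0.1, 4) == 1   # floor at one
        assert mg.resolve_n_replace(3, 15) == 3

    def test_budget_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            mg.binarize_topk(np.asarray([0.5, 0.5]), 3, 2)

    def test_sampled_positions_follow_scores(self, rng):
        # enumeration oracle: with k=1 the draw is categorical on p/Z
        p = np.asarray([0.7, 0.2, 0.1])
        counts = np.zeros(3)
        for _ in range(3000):
            counts[mg.sample_positions(p, 1, 3, rng)[0]] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - p) < 0.04)


class TestMaskApply:
    def test_zero_mask_is_identity(self, donor_dataset):
        seq = donor_dataset[0]
        out = mg.mask_apply(np.zeros(15, dtype=int), seq)
        assert np.array_equal(out.token_ids, seq.token_ids)
        assert out.n_blanks == 0

    def test_single_position_becomes_blank(self, donor_dataset, dna):
        seq = donor_dataset[0]
        mask = np.zeros(15, dtype=int)
        mask[1] = 1  # x_2 in 1-based terms
        out = mg.mask_apply(mask, seq)
        assert out.token_ids[1] == dna.blank_id
        assert np.array_equal(out.token_ids[2:], seq.token_ids[2:])
        assert out.token_ids[0] == seq.token_ids[0]

    def test_all_ones_blanks_everything(self, donor_dataset, dna):
        seq = donor_dataset[0]
        out = mg.mask_apply(np.ones(15, dtype=int), seq)
        assert np.all(out.token_ids == dna.blank_id)

    def test_length_mismatch_rejected(self, donor_dataset):
        with pytest.raises(ValueError):
            mg.mask_apply(np.zeros(7, dtype=int), donor_dataset[0])


class TestInfiller:
    def test_no_blanks_is_copy_through(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=2).fit()
        X, lengths, _ = donor_dataset.to_arrays()
        filled, _ = mut.infiller_.fill(X[:4], np.zeros_like(X[:4]),
                                       lengths[:4])
        assert np.array_equal(filled, X[:4])

    def test_blanks_replaced_by_real_vocabulary(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=2).fit()
        X, lengths, _ = donor_dataset.to_arrays()
        batch = mut.sample(X[:8], lengths[:8], n_replace=3,
                           rng=np.random.default_rng(1))
        assert batch.filled_X.shape == X[:8].shape
        changed = batch.filled_X[batch.masks == 1]
        assert np.all(changed >= 2)  # never pad (0) or blank (1)

    def test_forced_output_projection_argmax(self, dna):
        # push one token's logit far above the rest: greedy must emit it
        mut = mg.SequenceMutator(alphabet=dna, exclude_source=False,
                                 random_state=4).fit()
        target = dna.index("T")
        mut.infiller_.out.b.data[...] = 0.0
        mut.infiller_.out.b.data[target] = 50.0
        X = dna.encode("ACGTACG")[None, :]
        masks = np.zeros_like(X)
        masks[0, [1, 4]] = 1
        filled, _ = mut.infiller_.fill(X, masks, np.asarray([7]),
                                       mode="greedy", exclude_source=False,
                                       fill_ids=mut.fill_ids_)
        assert np.all(filled[0, [1, 4]] == target)

    def test_exclude_source_forces_a_change(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 exclude_source=True, random_state=2).fit()
        X, lengths, _ = donor_dataset.to_arrays()
        batch = mut.sample(X[:20], lengths[:20], n_replace=3,
                           rng=np.random.default_rng(5))
        diffs = (batch.filled_X != batch.source_X).astype(int)
        assert np.array_equal(diffs, batch.masks)


class TestEndToEnd:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 5))
    def test_mutant_differs_only_inside_mask(self, seed, k):
        spec = mg.CompositionSpec(counts={"DP": 4}, seed=seed % 100)
        ds = mg.generate_nn269_mimic(spec)
        mut = mg.SequenceMutator(alphabet=ds.alphabet, random_state=7).fit()
        X, lengths, _ = ds.to_arrays()
        batch = mut.sample(X, lengths, n_replace=k,
                           rng=np.random.default_rng(seed))
        assert np.all(batch.masks.sum(axis=1) == k)
        diffs = (batch.filled_X != batch.source_X).astype(int)
        # diff set equals the mask (exclude_source default on)
        assert np.array_equal(diffs, batch.masks)

    def test_greedy_transform_deterministic(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 n_replace=3, random_state=9).fit()
        X, lengths, _ = donor_dataset.to_arrays()
        a = mut.transform(X[:6], lengths[:6])
        b = mut.transform(X[:6], lengths[:6])
        assert np.array_equal(a, b)

    def test_plan_invariants(self, donor_dataset):
        mut = mg.SequenceMutator(alphabet=donor_dataset.alphabet,
                                 random_state=9).fit()
        plan = mut.plan(donor_dataset[0], n_replace=0.2)
        assert plan.n_replace == 3
        assert plan.mask.sum() == 3
        assert np.all((plan.p >= 0) & (plan.p <= 1))

    def test_action_log_prob_matches_sampling_frequency(self, tiny_mutator):
        # empirical check that exp(where_logp) is the true draw probability
        X = np.repeat(np.asarray([[2, 3, 4]]), 1000, axis=0)
        lengths = np.full(1000, 3)
        counts: dict[int, int] = {}
        logps: dict[int, float] = {}
        rng = np.random.default_rng(11)
        n = 4000
        for _ in range(n // 1000):
            b = tiny_mutator.sample(X, lengths, n_replace=1, rng=rng,
                                    want_logp=True)
            for row in range(1000):
                pos = int(b.positions[row, 0])
                counts[pos] = counts.get(pos, 0) + 1
                logps[pos] = float(b.where_logp.data[row])
        for pos, c in counts.items():
            prob = np.exp(logps[pos])
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(c / n - prob) < 4 * se + 0.01
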