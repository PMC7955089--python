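# Methods

## The model

`mutgan` implements a layered adversarial framework for discrete token
sequences. Two generators mutate a sequence; two discriminators learn to
undo the deception:

* **Position selector** (`G_where` in the usual GAN-for-text notation):
  embedding (50-d), two bidirectional recurrent layers (32 units each,
  LSTM cells by default), a dense layer (16 units, ReLU) and a per-position
  sigmoid. Its output `p = (p_1, …, p_M)` is the probability that each
  position should be replaced; padding positions are forced to 0.
* **Binarisation** `f(p) ∘ x`: the `N_replace` budget (a fraction of the
  true length or an absolute count) is resolved to `k` and `k` positions
  are selected — deterministically (top-k, lowest index wins ties) at
  inference, or drawn without replacement proportionally to `p + ε`
  (ε = 1e-8, Gumbel top-k realisation) during training so that the policy
  gradient has exploration. Selected positions become a reserved blank
  token.
* **Infiller** (`G_replace`): a GRU encoder–decoder with additive
  attention. The encoder (two GRU layers, 64 units) reads the blanked
  sequence. At each output step the decoder state attends over all encoder
  annotations — scores `e_tj = v·tanh(W s_{t−1} + U h_j)`, weights
  `α_tj = exp(e_tj)/Σ_k exp(e_tk)`, context `c_t = Σ_j α_tj h_j` — and two
  context-aware GRU layers (gates receive `C·c_t` terms, no bias, exactly
  the gate equations in the module docstrings) produce the state that is
  projected onto the vocabulary. **Only blank positions take their token
  from the decoder; all others copy the source token through**, so a
  mutant differs from its source in at most `k` positions. An LSTM variant
  of both the selector cells and the infiller (architecture
  EM-32-32-EM-32-32-OUT) is available through the `*_cell` parameters.
* **Explainer** (`D_explain`): same architecture family as the selector;
  per-position probability that the token was replaced. Padding is
  excluded from its loss and metrics.
* **Classifier** (`D_classify`): text-CNN — embedding, two convolutional
  layers (32 then 64 filters), dense 16, softmax head (single sigmoid for
  binary problems, where the output is the probability of the clean pole).
  Kernel width 3, same-padding and max-over-time pooling are our choices;
  the architecture family fixes only the layer sizes.

The two discriminators share no parameters and are trained independently.

## Training

The generator pair cannot be trained by backpropagating through the
discrete sampling steps, so it is trained with the score-function
(REINFORCE) estimator on a **terminal reward** granted once per completed
mutant:

    Q = D_classify(x^replace) − D_explain(x^replace)

* the classification component is the probability that the mutant is
  classified as clean/unmodified (per labeling rule, see below);
* the explanation component aggregates `D_explain`'s per-token outputs as
  the **mean over the truly replaced positions** (0 for an empty mask).
  Averaging over all positions instead is available by computing rewards
  from the full probability matrix; the mask-restricted mean is the
  default because it credits each undetected replacement individually.

Both generators maximise the same `Q` (their objectives share the reward),
with per-sample advantage `Q − b` where `b` is an exponential moving
average of `Q` (decay 0.9, on by default) — a variance reduction with no
effect on the estimator's mean. The gradient is
`∇ E[(Q−b)·log π(a)]` where `log π` is the exact log-probability of the
sampled action set: the ordered without-replacement position draw (chain of
renormalised categoricals) plus the decoder's log-softmax at each filled
blank. Unbiasedness is verified in the test suite against exhaustive
enumeration of all (mask, fill) outcomes on a vocabulary-3 / length-4
instance.

The discriminators minimise

    L_D = λ_explain · L_explain + λ_classify · L_classify

with `L_explain` the per-position binary cross-entropy against the
ground-truth replacement mask (clean records contribute all-zero masks;
padding excluded) and `L_classify` the label cross-entropy.
λ_explain = λ_classify = 1 by default.

The loop alternates: per epoch, `G_STEP` generator rounds then `D_STEP`
discriminator rounds per minibatch (both default 1). The classifier is
pretrained first on originals plus randomly masked-and-filled mutants at a
fixed 10% replacement fraction and then frozen (config can unfreeze); a
frozen classifier's loss term is skipped in the discriminator rounds since
it receives no updates. During adversarial training the replacement
fraction anneals linearly from 50% to 10% of the true length across
epochs, which keeps the explainer's positive class from starving early.
Early stopping monitors validation explanation macro-F1 (patience 5); the
best epoch's **selector, infiller and explainer are snapshotted together**
— an explainer is only meaningful against the generator distribution it
was trained on. The per-epoch validation mutants are drawn with one fixed
seed so that best-epoch selection tracks the models rather than sampling
noise. A non-finite loss aborts training.

## Labeling rules for augmentation

One mutant is generated per source record (so the augmented corpus is
exactly twice the source), each carrying its ground-truth mask:

* `two_class` — every mutant takes the designated generated-class label
  (e.g. the rumor class in rumor detection);
* `primed` — a mutant of a class-`Y` record is labelled `Y'`;
* `gene_merge` — primed labels are collapsed back onto the originals, the
  noise-resistance setting used for splice-site windows (an unmerged
  primed head is simply the `primed` rule with a 4- or 8-class
  classifier).

For splice-site augmentation the budget is 9 replacements per 90-nt
acceptor window and 3 per 15-nt donor window. Because these budgets are
exact Hamming distances, the infiller excludes the source token from the
substitute distribution by default (`exclude_source=True`, renormalised
softmax); substitutes may include the extended symbols N and S, mirroring
the non-canonical residues such mutants carry. The enumeration-oracle
tests disable the exclusion so that all (mask, fill) pairs are reachable.

## Synthetic data

No external corpus is needed; `mutgan.synth` provides two generators, both
bit-deterministic under a master seed (per-class streams are derived by
fixed offsets).

**Splice-site mimic.** Fixed-length windows over A/C/G/T: 90-nt
acceptor-like and 15-nt donor-like types. Positives carry a degenerate
consensus (acceptor: a pyrimidine-rich 10-mer ending in AG; donor: CAG
followed by the GT-led intron core) at a fixed centred offset, each
consensus base emitted with probability 0.9 and the remainder uniform;
negatives are uniform background. The default composition is the NN269
benchmark's: 5643 + 1342 acceptors and 4922 + 1324 donors, 13231 records
(the widely quoted acceptor-negative count of 1324 is inconsistent with
the benchmark totals — 1342 reconciles them — and remains available via
`printed_subclass_counts=True`). The generator reproduces only the
statistical shape of the benchmark: fixed window lengths, class
composition, and a learnable motif. It does **not** model branch points,
polypyrimidine-tract length variation, positional composition gradients or
genome-scale decoy structure, so passing tests demonstrate that the
machinery learns and explains planted signal — not that it would match the
published operating points on the real benchmark.

**Word corpus.** Markov-chain token sequences over a synthetic vocabulary
with a planted keyword set: positives contain at least one keyword,
negatives none, so labels are recomputable by a keyword scan. This is a
fixture for word-mode plumbing (length cap 40, tail padding / tail
truncation), not an emulation of social-media text.

## Numerical choices

* Float64 throughout; overflow-safe sigmoid; log-softmax with max
  subtraction; probabilities clipped to [1e-7, 1−1e-7] inside
  cross-entropies.
* Glorot-uniform initialisation; embeddings N(0, 0.1); a hook accepts
  externally trained 50-d token vectors but nothing is downloaded.
* Adam (lr 1e-3, β = 0.9/0.999), global gradient-norm clip 5, batch 32.
* Fraction budgets resolve by round-half-up with a floor of one
  replacement; `1 ≤ k ≤ M` is enforced.
* Top-k ties break to the lowest index; positions are 0-based and
  intervals half-open everywhere (rendered output may bracket tokens but
  never renumbers).
* Attention scores at padding positions get −1e9 before the softmax.
* The bidirectional wrapper reverses each row within its true length, so
  padding never seeds the reverse recursion.

## Problem sizes

The test suite and the acceptance script exercise the full loop on a
2000-sequence donor-window mimic (90/10 stratified hold-out, 20 epochs,
patience 5), where training takes a few minutes on one CPU and the
explainer reaches ≈0.7–0.85 held-out position-level macro-F1 with
classifier AUROC ≈0.98 on clean held-out windows. The estimator-level
checks (scalar-oracle equivalence, enumeration-oracle unbiasedness at
50,000 samples) run at toy sizes where exhaustive enumeration is exact.

## Known limitations

* CPU-only NumPy implementation: practical for the window lengths the
  splice-site setting uses (≤ 90 tokens) and the 40-token word fixture,
  not for long documents.
* The adversarial equilibrium is seed-dependent; held-out explanation
  macro-F1 varies by roughly ±0.1 across master seeds at the desk scale
  above.
* `D_classify` probabilities are uncalibrated; the clean-pole convention
  for binary heads is a labelling convention, not a calibrated posterior.
* Per-time-step credit assignment beyond the explainer's per-token
  signal (e.g. rollout-based intermediate rewards) is out of scope — the
  terminal reward approximates the long-term reward, which is adequate
  here precisely because only a few blanks are filled per sequence.
* Hierarchical attention and coupling the two discriminators are not
  implemented.
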