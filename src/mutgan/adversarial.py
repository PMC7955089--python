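"""Adversarial training: rewards, policy gradients, losses, augmentation.

The generator is trained with the score-function (REINFORCE) estimator on a
terminal reward granted once per completed sequence:

    Q = D_classify(x^replace) - D_explain(x^replace)

where the classification component is the probability that the mutant is
classified as clean/unmodified and the explanation component is the mean of
the per-position detection probabilities over the truly replaced positions.
Q therefore lies in [-1, 1]: the generator is rewarded for mutants that
keep a clean classification and whose edits go undetected.

The discriminators are trained with the weighted sum

    L_D = lambda_explain * L_explain + lambda_classify * L_classify,

L_explain being per-position binary cross-entropy against the ground-truth
replacement mask (padding excluded) and L_classify the cross-entropy of the
sequence labels.  Training alternates: per epoch the generators take
``g_step`` update rounds, then the discriminators ``d_step`` rounds, with
the replacement fraction annealed linearly between configured endpoints.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .alphabet import Alphabet
from .discriminator import MutationExplainer, SequenceClassifier, bce_loss
from .generator import MutationBatch, SequenceMutator, resolve_n_replace
from .metrics import auroc, explanation_f1, macro_f1, make_splits
from .sequence import GeneratedSequence, SequenceDataset
from .synth import ACCEPTOR_LENGTH, DONOR_LENGTH

__all__ = [
    "RewardSignal", "PolicySample", "TrainConfig", "RunningBaseline",
    "sequence_reward", "reinforce_update", "discriminator_loss",
    "pretrain_classifier", "augment_dataset", "primed_label",
    "AdversarialAugmenter", "NN269_REPLACE",
]

# replacement budgets of the splice-site augmentation: 9 characters per
# 90-nt acceptor window, 3 per 15-nt donor window
NN269_REPLACE = {ACCEPTOR_LENGTH: 9, DONOR_LENGTH: 3}


@dataclass
class RewardSignal:
    """Terminal reward for one completed mutant."""

    explain_component: float
    classify_component: float

    @property
    def Q(self) -> float:
        return self.classify_component - self.explain_component

    @property
    def R_T(self) -> float:
        return self.Q


@dataclass
class PolicySample:
    """One sampled generator action set with its log-probabilities."""

    source_ids: np.ndarray
    positions: np.ndarray
    fill_tokens: np.ndarray
    where_logp: float
    replace_logp: float


def primed_label(label: str) -> str:
    """Label of a machine-modified sequence derived from class ``label``."""
    return f"{label}'"


def _clean_component(probs: np.ndarray, classes: np.ndarray,
                     labeling: str, source_labels,
                     clean_label: str | None) -> np.ndarray:
    """Probability that each mutant is classified as clean/unmodified."""
    classes = np.asarray(classes, dtype=object).astype(str)
    if labeling == "two_class":
        if clean_label is None:
            raise ValueError("two_class labeling needs the clean label")
        col = int(np.flatnonzero(classes == str(clean_label))[0])
        return probs[:, col]
    if labeling == "primed":
        unprimed = ~np.char.endswith(classes.astype(str), "'")
        return probs[:, unprimed].sum(axis=1)
    if labeling == "gene_merge":
        col_of = {c: i for i, c in enumerate(classes)}
        cols = np.asarray([col_of[str(lbl)] for lbl in source_labels])
        return probs[np.arange(len(cols)), cols]
    raise ValueError(f"unknown labeling rule {labeling!r}")


def sequence_reward(filled_X: np.ndarray, truth_masks: np.ndarray,
                    lengths: np.ndarray, explainer: MutationExplainer,
                    classifier: SequenceClassifier, labeling: str,
                    source_labels=None, clean_label: str | None = None
                    ) -> list[RewardSignal]:
    """Score completed mutants with both discriminators.

    The explanation component is the mean detection probability over the
    truly replaced positions (0 when the mask is empty); the classification
    component is the clean-class probability under the selected labeling
    rule.
    """
    masks = np.asarray(truth_masks)
    explain_probs = explainer.predict_proba(filled_X, lengths)
    counts = masks.sum(axis=1)
    sums = (explain_probs * masks).sum(axis=1)
    explain = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    probs = classifier.predict_proba(filled_X, lengths)
    classify = _clean_component(probs, classifier.classes_, labeling,
                                source_labels, clean_label)
    return [RewardSignal(float(e), float(c))
            for e, c in zip(explain, classify)]


class RunningBaseline:
    """Exponential moving average of Q used as the REINFORCE baseline."""

    def __init__(self, decay: float = 0.9, enabled: bool = True):
        self.decay = decay
        self.enabled = enabled
        self.value: float | None = None

    def update(self, rewards: np.ndarray) -> float:
        if not self.enabled:
            return 0.0
        batch_mean = float(np.mean(rewards))
        self.value = (batch_mean if self.value is None
                      else self.decay * self.value
                      + (1.0 - self.decay) * batch_mean)
        return self.value


def reinforce_update(batch: MutationBatch, rewards, optimizer: nn.Adam,
                     target: str, baseline: float = 0.0) -> float:
    """Score-function update of one generator on a sampled batch.

    Maximises ``E[(Q - b) * log pi(a)]`` by minimising its negation; the
    batch must have been sampled with ``want_logp=True`` so the
    log-probability graph is alive.  Returns the loss value.
    """
    if len(batch) == 0:
        return 0.0
    if isinstance(rewards, (list, tuple)):
        rewards = np.asarray([r.Q if isinstance(r, RewardSignal) else r
                              for r in rewards], dtype=float)
    advantage = np.asarray(rewards, dtype=float) - baseline
    if target == "where":
        logp = batch.where_logp
    elif target == "replace":
        logp = batch.replace_logp
    else:
        raise ValueError(f"unknown policy-gradient target {target!r}")
    if logp is None:
        raise ValueError("batch was sampled without log-probabilities")
    loss = -(logp * nn.Tensor(advantage)).mean()
    if not np.isfinite(loss.data):
        raise RuntimeError("non-finite policy-gradient loss")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return float(loss.data)


def discriminator_loss(X: np.ndarray, masks: np.ndarray, labels,
                       lengths: np.ndarray, explainer: MutationExplainer,
                       classifier: SequenceClassifier,
                       lambda_explain: float = 1.0,
                       lambda_classify: float = 1.0) -> nn.Tensor:
    """Weighted discriminator loss on a mixed clean+generated batch.

    Every generated record must carry its truth mask; clean records carry
    all-zero masks.  Padding positions are excluded from the explanation
    term.
    """
    if lambda_explain == 0.0 and lambda_classify == 0.0:
        raise ValueError("at least one of the loss weights must be nonzero")
    X = np.asarray(X, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    total = nn.Tensor(np.zeros(()))
    if lambda_explain != 0.0:
        probs = explainer.net_.forward(X, lengths)
        valid = (np.arange(X.shape[1])[None, :]
                 < lengths[:, None]).astype(float)
        total = total + lambda_explain * bce_loss(probs, masks, weights=valid)
    if lambda_classify != 0.0:
        codes = classifier._encode_labels(labels)
        total = total + lambda_classify * classifier.loss(X, codes, lengths)
    return total


@dataclass
class TrainConfig:
    """Hyperparameters of the alternating adversarial loop."""

    epochs: int = 20
    g_step: int = 1
    d_step: int = 1
    lambda_explain: float = 1.0
    lambda_classify: float = 1.0
    n_replace_start: float = 0.5
    n_replace_end: float = 0.1
    pretrain_epochs: int = 8
    pretrain_n_replace: float = 0.1
    lr: float = 1e-3
    batch_size: int = 32
    patience: int = 5
    seed: int = 0
    baseline: bool = True
    baseline_decay: float = 0.9
    labeling: str = "gene_merge"
    clean_label: str | None = None
    freeze_classifier: bool = True
    holdout_fraction: float = 0.1
    augment_n_replace: "int | float | dict | None" = None

    def __post_init__(self):
        if self.n_replace_start < self.n_replace_end:
            raise ValueError("the replacement schedule anneals downwards: "
                             "start must be >= end")
        if self.lambda_explain == 0.0 and self.lambda_classify == 0.0:
            raise ValueError("loss weights cannot both be zero")

    def n_replace_at(self, epoch: int) -> float:
        """Linear anneal of the replacement fraction across epochs."""
        if self.epochs <= 1:
            return self.n_replace_end
        frac = epoch / (self.epochs - 1)
        return (self.n_replace_start
                + (self.n_replace_end - self.n_replace_start) * frac)


def _augment_label_fn(labeling: str, generated_label: str | None):
    if labeling == "two_class":
        if generated_label is None:
            raise ValueError("two_class labeling needs the generated-class "
                             "label (e.g. the rumor class)")
        return lambda y: generated_label
    if labeling == "primed":
        return primed_label
    if labeling == "gene_merge":
        return lambda y: y
    raise ValueError(f"unknown labeling rule {labeling!r}")


def _random_mutants(dataset: SequenceDataset, fraction, fill_ids: np.ndarray,
                    rng: np.random.Generator, label_fn
                    ) -> list[GeneratedSequence]:
    """Random-policy mutants (uniform positions, uniform fills ≠ source)."""
    out = []
    for seq in dataset:
        k = resolve_n_replace(fraction, seq.length)
        pos = rng.choice(seq.length, size=k, replace=False)
        ids = seq.token_ids.copy()
        for j in pos:
            options = fill_ids[fill_ids != ids[j]]
            ids[j] = rng.choice(options)
        mask = np.zeros(seq.padded_length, dtype=np.int64)
        mask[pos] = 1
        out.append(GeneratedSequence(
            id=f"{seq.id}~rnd", token_ids=ids, length=seq.length,
            source_id=seq.id, truth_mask=mask, label=label_fn(seq.label)))
    return out


def pretrain_classifier(dataset: SequenceDataset, config: TrainConfig,
                        classifier: SequenceClassifier | None = None
                        ) -> SequenceClassifier:
    """Train D_classify on originals plus randomly masked-and-filled mutants.

    The random policy fixes the replacement fraction (default 10% of the
    true length) so the classifier sees the mutated-data distribution
    before the generators are trained; it is frozen afterwards unless the
    config says otherwise.
    """
    rng = np.random.default_rng(config.seed + 11)
    label_fn = _augment_label_fn(config.labeling, _generated_label(config))
    mutants = _random_mutants(dataset, config.pretrain_n_replace,
                              dataset.alphabet.fill_ids(), rng, label_fn)
    all_seqs = dataset.extend(SequenceDataset(
        [m.as_token_sequence() for m in mutants], dataset.alphabet))
    X, lengths, y = all_seqs.to_arrays()
    if len(np.unique(y.astype(str))) < 2:
        raise ValueError("pretraining needs at least two classes after "
                         "augmentation")
    if classifier is None:
        classifier = SequenceClassifier(
            alphabet=dataset.alphabet, lr=config.lr,
            batch_size=config.batch_size, epochs=config.pretrain_epochs,
            positive_label=config.clean_label, random_state=config.seed + 12)
    classifier.fit(X, y, lengths=lengths)
    if config.freeze_classifier:
        classifier.freeze()
    return classifier


def _generated_label(config: TrainConfig) -> str | None:
    # the designated label of machine-generated records in two-class mode
    return "R" if config.labeling == "two_class" else None


def augment_dataset(dataset: SequenceDataset, mutator: SequenceMutator,
                    labeling: str = "gene_merge", n_replace=None,
                    mode: str = "sample", seed: int = 0,
                    generated_label: str | None = None
                    ) -> list[GeneratedSequence]:
    """One mutant per source record, labelled by the selected rule.

    ``two_class``: every mutant takes the designated generated-class label;
    ``primed``: label Y becomes Y'; ``gene_merge``: the primed classes are
    collapsed back onto the originals (label unchanged).
    """
    label_fn = _augment_label_fn(labeling, generated_label)
    rng = np.random.default_rng(seed)
    if n_replace is None:
        n_replace = NN269_REPLACE
    return mutator.mutate_sequences(list(dataset), n_replace=n_replace,
                                    mode=mode, rng=rng, label_fn=label_fn)


def _jsonable(record: dict) -> dict:
    return {k: (float(v) if isinstance(v, (np.floating, float)) else v)
            for k, v in record.items()}


class AdversarialAugmenter(BaseEstimator):
    """The full layered adversarial model as one fit-able estimator.

    ``fit`` pretrains the classifier, then alternates generator
    (policy-gradient) and discriminator (supervised) update rounds, keeping
    the best explainer by validation macro-F1 with early stopping.
    Fitted attributes: ``mutator_``, ``explainer_``, ``classifier_``,
    ``history_`` and the train/validation index split.
    """

    def __init__(self, alphabet: Alphabet | None = None,
                 config: TrainConfig | None = None,
                 where_cell: str = "lstm", replace_cell: str = "gru",
                 generated_label: str | None = None):
        self.alphabet = alphabet
        self.config = config
        self.where_cell = where_cell
        self.replace_cell = replace_cell
        self.generated_label = generated_label

    # -- helpers -------------------------------------------------------------

    def _eval_sets(self, val: SequenceDataset, cfg: TrainConfig,
                   seed: int):
        """Held-out mutants (for the explainer) and originals (classifier)."""
        mutants = augment_dataset(
            val, self.mutator_, labeling=cfg.labeling,
            n_replace=cfg.augment_n_replace, mode="sample", seed=seed,
            generated_label=self.generated_label)
        Xm = np.stack([m.token_ids for m in mutants])
        lm = np.asarray([m.length for m in mutants])
        masks = np.stack([m.truth_mask for m in mutants])
        return mutants, Xm, lm, masks

    def _val_explain_f1(self, cfg, seed, val) -> float:
        _, Xm, lm, masks = self._eval_sets(val, cfg, seed)
        probs = self.explainer_.predict_proba(Xm, lm)
        return explanation_f1(list(masks), list(probs), lengths=lm)

    # -- fitting -------------------------------------------------------------

    def fit(self, dataset: SequenceDataset, y=None):
        cfg = self.config or TrainConfig()
        self.config_ = cfg
        rng = np.random.default_rng(cfg.seed)
        alphabet = self.alphabet or dataset.alphabet

        splits = make_splits(dataset.labels, "holdout",
                             test_size=cfg.holdout_fraction, seed=cfg.seed)
        train_idx, val_idx = splits[0]
        self.train_idx_, self.val_idx_ = train_idx, val_idx
        train, val = dataset.subset(train_idx), dataset.subset(val_idx)

        # stage 1: pretrain and freeze the classifier
        self.classifier_ = pretrain_classifier(train, cfg)

        # stage 2: build generators and explainer
        self.mutator_ = SequenceMutator(
            alphabet=alphabet, where_cell=self.where_cell,
            replace_cell=self.replace_cell,
            random_state=cfg.seed + 21).fit()
        self.explainer_ = MutationExplainer(
            alphabet=alphabet, cell=self.where_cell, lr=cfg.lr,
            batch_size=cfg.batch_size,
            random_state=cfg.seed + 22).initialize()
        opt_where = nn.Adam(self.mutator_.selector_.parameters(), lr=cfg.lr)
        opt_replace = nn.Adam(self.mutator_.infiller_.parameters(), lr=cfg.lr)
        opt_explain = self.explainer_.optimizer_
        baseline = RunningBaseline(cfg.baseline_decay, cfg.baseline)
        label_fn = _augment_label_fn(cfg.labeling, self.generated_label
                                     or _generated_label(cfg))
        # a frozen classifier receives no updates, so its loss term would
        # only burn compute inside the discriminator rounds
        lam_classify = 0.0 if self.classifier_.frozen_ else cfg.lambda_classify

        X, lengths, labels = train.to_arrays()
        n = X.shape[0]
        history: list[dict] = []
        best_f1, best_state, best_epoch = -1.0, None, -1
        order_rng = np.random.default_rng(cfg.seed + 31)
        sample_rng = np.random.default_rng(cfg.seed + 32)
        # one fixed draw seed for every epoch's validation mutants, so
        # best-epoch selection tracks the models, not the sampling noise
        eval_seed = cfg.seed + 33

        for epoch in range(cfg.epochs):
            frac = cfg.n_replace_at(epoch)
            order = order_rng.permutation(n)
            g_losses, d_losses, qs = [], [], []
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                Xb, lb = X[idx], lengths[idx]
                yb = labels[idx]
                batch = None
                for _ in range(cfg.g_step):
                    batch = self.mutator_.sample(
                        Xb, lb, n_replace=frac, rng=sample_rng,
                        mode="sample", want_logp=True)
                    rewards = sequence_reward(
                        batch.filled_X, batch.masks, lb, self.explainer_,
                        self.classifier_, cfg.labeling, source_labels=yb,
                        clean_label=cfg.clean_label)
                    q = np.asarray([r.Q for r in rewards])
                    qs.append(q.mean())
                    b = baseline.update(q)
                    lw = reinforce_update(batch, q, opt_where, "where", b)
                    lr_ = reinforce_update(batch, q, opt_replace, "replace", b)
                    g_losses.append(lw + lr_)
                if batch is None:  # g_step == 0: still need mutants for D
                    batch = self.mutator_.sample(Xb, lb, n_replace=frac,
                                                 rng=sample_rng, mode="sample")
                if cfg.lambda_explain == 0.0 and lam_classify == 0.0:
                    continue
                for _ in range(cfg.d_step):
                    Xd = np.concatenate([Xb, batch.filled_X])
                    md = np.concatenate([np.zeros_like(batch.masks),
                                         batch.masks])
                    ld = np.concatenate([lb, lb])
                    yd = np.concatenate([yb, [label_fn(l) for l in yb]])
                    loss = discriminator_loss(
                        Xd, md, yd, ld, self.explainer_, self.classifier_,
                        cfg.lambda_explain, lam_classify)
                    if not np.isfinite(loss.data):
                        raise RuntimeError("non-finite discriminator loss")
                    opt_explain.zero_grad()
                    if not self.classifier_.frozen_:
                        self.classifier_.optimizer_.zero_grad()
                    loss.backward()
                    opt_explain.step()
                    if not self.classifier_.frozen_:
                        self.classifier_.optimizer_.step()
                    d_losses.append(float(loss.data))

            val_f1 = self._val_explain_f1(cfg, eval_seed, val)
            record = {
                "epoch": epoch, "n_replace_frac": frac,
                "mean_Q": float(np.mean(qs)) if qs else None,
                "g_loss": float(np.mean(g_losses)) if g_losses else None,
                "d_loss": float(np.mean(d_losses)) if d_losses else None,
                "val_explain_macro_f1": val_f1,
            }
            history.append(_jsonable(record))
            if val_f1 > best_f1:
                best_f1, best_epoch = val_f1, epoch
                # snapshot generators and explainer together: the explainer
                # is only meaningful against the generator it was trained on
                best_state = {
                    "explainer": self.explainer_.net_.state_dict(),
                    "selector": self.mutator_.selector_.state_dict(),
                    "infiller": self.mutator_.infiller_.state_dict(),
                }
            elif epoch - best_epoch >= cfg.patience:
                break

        if best_state is not None:
            self.explainer_.net_.load_state_dict(best_state["explainer"])
            self.mutator_.selector_.load_state_dict(best_state["selector"])
            self.mutator_.infiller_.load_state_dict(best_state["infiller"])
        self.history_ = history
        self.best_val_explain_f1_ = best_f1
        return self

    # -- downstream API ------------------------------------------------------

    def augment(self, dataset: SequenceDataset, n_replace=None,
                mode: str = "sample", seed: int = 0
                ) -> list[GeneratedSequence]:
        cfg = self.config_
        return augment_dataset(
            dataset, self.mutator_, labeling=cfg.labeling,
            n_replace=n_replace if n_replace is not None
            else cfg.augment_n_replace,
            mode=mode, seed=seed, generated_label=self.generated_label)

    def save_history(self, path) -> None:
        with open(path, "w") as fh:
            for record in self.history_:
                fh.write(json.dumps(record) + "\n")
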