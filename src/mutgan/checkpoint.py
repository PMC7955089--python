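"""Checkpoint directories: versioned parameter blobs plus a JSON manifest.

A checkpoint directory holds one ``.npz`` per model (selector, infiller,
explainer, classifier) and a ``manifest.json`` recording the architecture
strings, the alphabet, the estimator hyperparameters and the training
config — enough to rebuild every estimator and reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .adversarial import TrainConfig
from .alphabet import Alphabet
from .discriminator import MutationExplainer, SequenceClassifier
from .generator import SequenceMutator

__all__ = ["save_models", "load_models", "write_manifest"]

FORMAT_VERSION = 1


def _alphabet_spec(alphabet: Alphabet) -> dict:
    return {"tokens": list(alphabet.tokens),
            "extended": list(alphabet.extended),
            "delimiter": alphabet.delimiter}


def _alphabet_from_spec(spec: dict) -> Alphabet:
    return Alphabet(tokens=tuple(spec["tokens"]),
                    extended=tuple(spec["extended"]),
                    delimiter=spec["delimiter"])


def _params(estimator) -> dict:
    params = estimator.get_params(deep=False)
    params.pop("alphabet", None)
    params.pop("config", None)
    if isinstance(params.get("n_replace"), dict):
        params["n_replace"] = {str(k): v
                               for k, v in params["n_replace"].items()}
    for key, value in params.items():
        if isinstance(value, tuple):
            params[key] = list(value)
    return params


def _restore_params(params: dict) -> dict:
    out = dict(params)
    if isinstance(out.get("n_replace"), dict):
        out["n_replace"] = {int(k): v for k, v in out["n_replace"].items()}
    for key, value in out.items():
        if isinstance(value, list):
            out[key] = tuple(value)
    return out


def write_manifest(path, payload: dict) -> None:
    payload = {"format_version": FORMAT_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def save_models(directory, mutator: SequenceMutator | None = None,
                explainer: MutationExplainer | None = None,
                classifier: SequenceClassifier | None = None,
                config: TrainConfig | None = None,
                alphabet: Alphabet | None = None,
                extra: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"models": {}, "architectures": {}}
    if alphabet is None:
        for est in (mutator, explainer, classifier):
            if est is not None and hasattr(est, "alphabet_"):
                alphabet = est.alphabet_
                break
    if alphabet is not None:
        manifest["alphabet"] = _alphabet_spec(alphabet)
    if config is not None:
        manifest["train_config"] = asdict(config)
    if extra:
        manifest.update(extra)
    if mutator is not None:
        np.savez(directory / "selector.npz", **mutator.selector_.state_dict())
        np.savez(directory / "infiller.npz", **mutator.infiller_.state_dict())
        manifest["models"]["mutator"] = _params(mutator)
        manifest["architectures"]["selector"] = mutator.selector_.arch
        manifest["architectures"]["infiller"] = mutator.infiller_.arch
    if explainer is not None:
        np.savez(directory / "explainer.npz", **explainer.net_.state_dict())
        manifest["models"]["explainer"] = _params(explainer)
        manifest["architectures"]["explainer"] = explainer.architecture
    if classifier is not None:
        np.savez(directory / "classifier.npz",
                 **classifier.net_.state_dict())
        params = _params(classifier)
        params["classes"] = [str(c) for c in classifier.classes_]
        params["frozen"] = bool(classifier.frozen_)
        manifest["models"]["classifier"] = params
        manifest["architectures"]["classifier"] = classifier.architecture
    write_manifest(directory / "manifest.json", manifest)
    return directory


def load_models(directory) -> dict:
    """Rebuild every model stored in a checkpoint directory."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    alphabet = (_alphabet_from_spec(manifest["alphabet"])
                if "alphabet" in manifest else None)
    out: dict = {"manifest": manifest, "alphabet": alphabet}
    models = manifest.get("models", {})
    if "mutator" in models:
        mutator = SequenceMutator(alphabet=alphabet,
                                  **_restore_params(models["mutator"])).fit()
        mutator.selector_.load_state_dict(
            dict(np.load(directory / "selector.npz")))
        mutator.infiller_.load_state_dict(
            dict(np.load(directory / "infiller.npz")))
        out["mutator"] = mutator
    if "explainer" in models:
        explainer = MutationExplainer(
            alphabet=alphabet,
            **_restore_params(models["explainer"])).initialize()
        explainer.net_.load_state_dict(
            dict(np.load(directory / "explainer.npz")))
        out["explainer"] = explainer
    if "classifier" in models:
        params = _restore_params(models["classifier"])
        classes = np.asarray(params.pop("classes"), dtype=object)
        frozen = params.pop("frozen")
        classifier = SequenceClassifier(alphabet=alphabet, **params)
        classifier._build(classes)
        classifier.net_.load_state_dict(
            dict(np.load(directory / "classifier.npz")))
        classifier.frozen_ = frozen
        out["classifier"] = classifier
    if "train_config" in manifest:
        out["config"] = TrainConfig(**manifest["train_config"])
    return out
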