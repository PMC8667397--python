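"""Training loop, evaluation, checkpoints, and the ablation runner.

Training minimizes the truncated binary cross-entropy (or the plain mean BCE
when denoising is disabled) with Adam.  The drop-rate iteration counter T is
advanced per optimizer step.  Model selection is by validation micro-F1.
Three seeds govern a run independently: corpus generation (held by the
generator), parameter initialization (ModelConfig.seed) and batch shuffling
(TrainConfig.shuffle_seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .corpus import PAD_ID, EncodedDocument, Vocabulary
from .denoising import DenoiseConfig, truncation_step
from .metrics import MetricsReport, PredictionSet, full_report
from .model import ABLATION_MODES, JlanModel, ModelConfig

CHECKPOINT_SCHEMA = 1


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 10  # early stop on validation micro-F1
    shuffle_seed: int = 0
    eval_batch_size: int = 64
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    count_epochs: bool = False  # interpret the D_T counter T as epochs


@dataclass
class RunRecord:
    """Per-run log: loss/drop history and the chosen validation scores."""

    train_loss: list[float] = field(default_factory=list)  # per epoch
    kept_loss: list[float] = field(default_factory=list)  # mean loss over kept entries
    drop_rate: list[float] = field(default_factory=list)  # D_T at epoch end
    n_dropped: list[int] = field(default_factory=list)  # per epoch totals
    valid_micro_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    test_report: MetricsReport | None = None

    def iteration_log(self) -> list[dict]:
        return [
            {
                "epoch": i,
                "train_loss": self.train_loss[i],
                "kept_loss": self.kept_loss[i],
                "D_T": self.drop_rate[i],
                "n_dropped": self.n_dropped[i],
                "valid_micro_f1": self.valid_micro_f1[i] if self.valid_micro_f1 else None,
            }
            for i in range(len(self.train_loss))
        ]


class Adam:
    """Adam over a named parameter dict."""

    def __init__(self, params: Mapping[str, Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = dict(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        # PAD embedding row stays zero
        if "E" in self.params:
            self.params["E"].data[PAD_ID] = 0.0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# batching


def pad_batch(docs: Sequence[EncodedDocument]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-pad a batch to its longest document; returns (ids, mask, labels)."""
    n = max(d.n for d in docs)
    ids = np.full((len(docs), max(n, 1)), PAD_ID, dtype=np.int64)
    mask = np.zeros_like(ids, dtype=bool)
    labels = np.stack([d.label_vector for d in docs]).astype(np.float64)
    for i, d in enumerate(docs):
        ids[i, : d.n] = d.token_ids
        mask[i, : d.n] = True
    return ids, mask, labels


def _bce_entries_tensor(y: np.ndarray, y_hat: Tensor) -> Tensor:
    """Per-entry BCE as a differentiable graph (probabilities clamped)."""
    p = ag.clip(ag.sigmoid(y_hat), 1e-7, 1.0 - 1e-7)
    y_t = Tensor(y)
    return -(y_t * ag.log(p) + (1.0 - y_t) * ag.log(1.0 - p))


def predict_probs(model: JlanModel, docs: Sequence[EncodedDocument],
                  batch_size: int = 64) -> np.ndarray:
    """Deterministic probabilities for a document list (evaluation mode)."""
    out = []
    for start in range(0, len(docs), batch_size):
        ids, mask, _ = pad_batch(docs[start : start + batch_size])
        _, y_tilde, _ = model.forward(ids, mask, train=False)
        out.append(y_tilde.data)
    return np.concatenate(out, axis=0)


def evaluate(model: JlanModel, docs: Sequence[EncodedDocument],
             ks: tuple[int, ...] = (5, 8, 15), threshold: float = 0.5) -> MetricsReport:
    """Score a split and return the standard multi-label report."""
    if len(docs) == 0:
        raise ValueError("empty split")
    probs = predict_probs(model, docs)
    y_true = np.stack([d.label_vector for d in docs])
    return full_report(PredictionSet(y_true, probs, threshold), ks=ks)


# ---------------------------------------------------------------------------
# training


def train(
    model: JlanModel,
    train_docs: Sequence[EncodedDocument],
    valid_docs: Sequence[EncodedDocument] | None,
    config: TrainConfig,
    noise_mask: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], RunRecord]:
    """Train in place; returns (best parameter state, run record).

    When ``noise_mask`` (aligned with ``train_docs`` rows) is given, the
    per-epoch overlap between dropped entries and the known-noisy entries is
    appended to the record's iteration log via ``record.noise_hits`` — used by
    the denoising diagnostics.
    """
    if len(train_docs) == 0:
        raise ValueError("empty training split")
    record = RunRecord()
    record.noise_hits = []  # type: ignore[attr-defined]
    record.dropped_total = []  # type: ignore[attr-defined]
    best_state = model.state_dict()
    if config.max_epochs == 0:
        return best_state, record

    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.shuffle_seed)
    T = 0
    best_f1 = -1.0
    bad_epochs = 0
    idx_all = np.arange(len(train_docs))

    for epoch in range(config.max_epochs):
        order = rng.permutation(idx_all)
        epoch_loss = 0.0
        epoch_kept_loss = 0.0
        epoch_dropped = 0
        epoch_noise_hits = 0
        n_batches = 0
        last_DT = 0.0
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            batch = [train_docs[i] for i in batch_idx]
            ids, mask, y = pad_batch(batch)
            y_hat, y_tilde, _ = model.forward(ids, mask, train=True)

            step_T = epoch if config.count_epochs else T
            rep = truncation_step(y, y_tilde.data, step_T, config.denoise)
            entries = _bce_entries_tensor(y, y_hat)
            kept = rep.kept_mask.astype(np.float64)
            loss = (entries * Tensor(kept)).sum() * (1.0 / y.size)
            opt.zero_grad()
            loss.backward()
            opt.step()
            T += 1

            epoch_loss += float(loss.data)
            n_kept = int(rep.kept_mask.sum())
            epoch_kept_loss += float(
                np.where(rep.kept_mask, rep.bce, 0.0).sum() / max(n_kept, 1)
            )
            epoch_dropped += rep.n_dropped
            last_DT = rep.D_T
            n_batches += 1
            if noise_mask is not None:
                batch_noise = noise_mask[batch_idx]
                epoch_noise_hits += int((~rep.kept_mask & batch_noise).sum())

        record.train_loss.append(epoch_loss / n_batches)
        record.kept_loss.append(epoch_kept_loss / n_batches)
        record.drop_rate.append(last_DT)
        record.n_dropped.append(epoch_dropped)
        record.noise_hits.append(epoch_noise_hits)  # type: ignore[attr-defined]
        record.dropped_total.append(epoch_dropped)  # type: ignore[attr-defined]

        if valid_docs:
            rep_v = evaluate(model, valid_docs)
            record.valid_micro_f1.append(rep_v.micro_f1)
            if rep_v.micro_f1 > best_f1:
                best_f1 = rep_v.micro_f1
                best_state = model.state_dict()
                record.best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    break
        else:
            best_state = model.state_dict()
            record.best_epoch = epoch
    return best_state, record


# ---------------------------------------------------------------------------
# splits and checkpoints


def split_documents(
    docs: Sequence, fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Shuffle and split; splits are disjoint by construction (asserted)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    n_train = int(round(fractions[0] * len(docs)))
    n_valid = int(round(fractions[1] * len(docs)))
    tr = [docs[i] for i in order[:n_train]]
    va = [docs[i] for i in order[n_train : n_train + n_valid]]
    te = [docs[i] for i in order[n_train + n_valid :]]
    ids = [d.doc_id for part in (tr, va, te) for d in part]
    if len(ids) != len(set(ids)):
        raise ValueError("doc_id appears in more than one split")
    return tr, va, te


def save_checkpoint(
    path: str | Path,
    model: JlanModel,
    vocab: Vocabulary,
    label_index: Mapping[str, int],
) -> None:
    """Single-file checkpoint: parameters + config + vocabulary hash."""
    import hashlib

    vocab_hash = hashlib.sha256(
        json.dumps(vocab.token_to_id, sort_keys=True).encode()
    ).hexdigest()
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": model.config_dict(),
        "vocab_hash": vocab_hash,
        "token_to_id": vocab.token_to_id,
        "label_index": dict(label_index),
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[JlanModel, Vocabulary, dict[str, int]]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError("unsupported checkpoint schema")
        state = {k: z[k] for k in z.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    model = JlanModel(config)
    model.load_state_dict(state)
    vocab = Vocabulary(dict(meta["token_to_id"]))
    return model, vocab, dict(meta["label_index"])


# ---------------------------------------------------------------------------
# ablations


def run_ablation(
    train_docs: Sequence[EncodedDocument],
    valid_docs: Sequence[EncodedDocument],
    test_docs: Sequence[EncodedDocument],
    base_model_config: ModelConfig,
    base_train_config: TrainConfig,
    modes: Sequence[str],
    seeds: Sequence[int],
    embeddings: np.ndarray | None = None,
) -> dict:
    """One run per (mode, seed); summary is the per-mode mean and sd.

    ``no_denoise`` reuses the full architecture with truncation disabled; the
    attention ablations keep the denoising settings of the base config.
    """
    import copy

    if not modes or not seeds:
        raise ValueError("need at least one mode and one seed")
    runs: dict[str, list[MetricsReport]] = {m: [] for m in modes}
    for mode in modes:
        if mode not in ABLATION_MODES + ("no_denoise",):
            raise ValueError(f"unknown ablation mode {mode!r}")
        for seed in seeds:
            mc = copy.deepcopy(base_model_config)
            tc = copy.deepcopy(base_train_config)
            mc.seed = seed
            tc.shuffle_seed = seed
            if mode == "no_denoise":
                mc.ablation = "full"
                tc.denoise = DenoiseConfig(enabled=False)
            else:
                mc.ablation = mode
            model = JlanModel(mc, embeddings=embeddings)
            best_state, _ = train(model, train_docs, valid_docs, tc)
            model.load_state_dict(best_state)
            runs[mode].append(evaluate(model, test_docs))
    summary = {}
    for mode, reports in runs.items():
        summary[mode] = {
            metric: {
                "mean": float(np.mean([getattr(r, metric) for r in reports])),
                "sd": float(np.std([getattr(r, metric) for r in reports])),
            }
            for metric in ("micro_f1", "macro_f1", "micro_auc", "macro_auc")
        }
    return {"runs": runs, "summary": summary}
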