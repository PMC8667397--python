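"""Reference desk-scale experiment protocols.

These functions pin down the study conditions used throughout the package's
own evaluation: corpus sizes, network dimensions and schedules small enough
to run on one CPU core in minutes, while preserving the statistical structure
of the task (long-tailed labels, trigger-token evidence, spurious-positive
annotation noise).  Both the test suite and the reproduction script call
these entry points, so the conditions cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoising import DenoiseConfig
from .model import JlanModel, ModelConfig
from .pipeline import encode_corpus
from .synthetic import SyntheticConfig, SyntheticCorpus, generate_corpus
from .training import TrainConfig, evaluate, run_ablation, train


def toy_corpus_config(seed: int, *, n_docs: int = 200, L_labels: int = 10,
                      noise_rate: float = 0.0) -> SyntheticConfig:
    """The toy corpus: 10 codes, 3 triggers per code, generator defaults
    elsewhere (30-60-token documents, Zipf exponent 1.2)."""
    return SyntheticConfig(
        L_labels=L_labels,
        vocab_size=300,
        n_docs=n_docs,
        noise_rate=noise_rate,
        seed=seed,
    )


def desk_model_config(L_labels: int, vocab_size: int, seed: int,
                      ablation: str = "full") -> ModelConfig:
    """Reduced network dimensions for CPU-scale experiments.

    The architecture is unchanged; only widths shrink (embedding 24, LSTM 16
    per direction, attention inner dim 16, MLP hidden 32).  Dropout is off so
    runs are exactly reproducible.
    """
    return ModelConfig(
        L_labels=L_labels, vocab_size=vocab_size, e_dim=24, k=16, d=16,
        mlp_hidden=32, dropout=0.0, seed=seed, ablation=ablation,
    )


# ---------------------------------------------------------------------------


@dataclass
class OverfitResult:
    train_micro_f1: float
    epochs_used: int
    model: JlanModel
    corpus: SyntheticCorpus
    vocab: object
    label_index: dict


def overfit_experiment(seed: int, max_epochs: int = 200,
                       check_every: int = 10, target: float = 0.95) -> OverfitResult:
    """Memorization sanity check: 200 documents, 10 codes, denoising off.

    Trains in ``check_every``-epoch chunks and stops as soon as training
    micro-F1 clears ``target`` (or the epoch budget runs out).
    """
    corpus = generate_corpus(toy_corpus_config(seed))
    enc, vocab, li = encode_corpus(corpus.documents)
    model = JlanModel(desk_model_config(len(li), len(vocab), seed))
    tc = TrainConfig(
        max_epochs=check_every, batch_size=16, shuffle_seed=seed,
        denoise=DenoiseConfig(enabled=False),
    )
    f1 = 0.0
    used = 0
    for _ in range(max_epochs // check_every):
        train(model, enc, None, tc)
        used += check_every
        f1 = evaluate(model, enc).micro_f1
        if f1 >= target:
            break
    return OverfitResult(f1, used, model, corpus, vocab, li)


def attention_trigger_mass(model: JlanModel, vocab, label_index: dict,
                           corpus_seed: int, n_eval_docs: int = 40) -> dict:
    """Label-attention mass on trigger tokens, on fresh held-out documents.

    Generates ``n_eval_docs`` unseen documents from the same corpus family,
    then for every (document, positive label) pair sums the label-attention
    weight over that label's trigger positions.  Returns the mean mass, the
    mean uniform baseline (trigger positions / document length), and their
    ratio; a model that has learned the task concentrates attention on the
    triggers, pushing the ratio well above 1.
    """
    cfg = toy_corpus_config(corpus_seed)
    eval_cfg = SyntheticConfig(
        **{**cfg.__dict__, "n_docs": n_eval_docs, "seed": cfg.seed + 9999}
    )
    held_out = generate_corpus(eval_cfg)
    enc, _, _ = encode_corpus(held_out.documents, label_index, vocab=vocab)
    masses, baselines = [], []
    per_label: dict[str, list[tuple[float, float, float]]] = {}
    for doc, enc_doc, y in zip(held_out.documents, enc, held_out.clean_labels):
        tokens = doc.text.split()[: enc_doc.n]
        _, _, bundle = model.forward(enc_doc.token_ids[None, :])
        for j in np.flatnonzero(y):
            code = held_out.codes[j]
            trigs = set(held_out.trigger_tokens[code])
            pos = [p for p, t in enumerate(tokens) if t in trigs]
            if not pos:
                continue
            mass = float(bundle.B_L[0, j, pos].sum())
            base = len(pos) / enc_doc.n
            masses.append(mass)
            baselines.append(base)
            per_label.setdefault(code, []).append((mass, base, 1.0 / enc_doc.n))
    mean_mass = float(np.mean(masses))
    mean_base = float(np.mean(baselines))
    return {
        "mean_trigger_mass": mean_mass,
        "uniform_baseline": mean_base,
        "ratio": mean_mass / mean_base,
        "n_pairs": len(masses),
        # per-label means: trigger mass, uniform trigger mass, 1/n
        "per_label_mass": {
            c: float(np.mean([m for m, _, _ in v])) for c, v in per_label.items()
        },
        "per_label_uniform": {
            c: float(np.mean([b for _, b, _ in v])) for c, v in per_label.items()
        },
        "per_label_inv_n": {
            c: float(np.mean([i for _, _, i in v])) for c, v in per_label.items()
        },
        "per_label_n": {c: len(v) for c, v in per_label.items()},
    }


# ---------------------------------------------------------------------------


def _noisy_splits(seed: int, n_docs: int = 700):
    """Corpus with 30% spurious-positive noise; clean labels on the test split."""
    cfg = toy_corpus_config(seed, n_docs=n_docs, noise_rate=0.3)
    corpus = generate_corpus(cfg)
    n_tr, n_va = int(0.72 * n_docs), int(0.14 * n_docs)
    enc_noisy, vocab, li = encode_corpus(corpus.noisy_documents()[:n_tr])
    enc_valid, _, _ = encode_corpus(
        corpus.noisy_documents()[n_tr : n_tr + n_va], li, vocab=vocab
    )
    enc_test, _, _ = encode_corpus(
        corpus.documents[n_tr + n_va :], li, vocab=vocab
    )
    return corpus, vocab, li, enc_noisy, enc_valid, enc_test, corpus.noise_mask[:n_tr]


def denoising_experiment(seeds=(0, 1, 2), epochs: int = 60) -> dict:
    """Truncation loss vs plain BCE on a 30%-noise corpus, clean-test scoring.

    For each seed both losses train the same architecture for the same number
    of epochs; the truncated run additionally records how often a dropped
    entry was one of the injected noisy positives, which is compared with the
    expected overlap of a size-matched uniformly random drop.
    """
    f1_denoise, f1_plain, overlap, random_overlap = [], [], [], []
    for seed in seeds:
        corpus, vocab, li, tr, va, te, nm = _noisy_splits(seed)
        for enabled in (True, False):
            model = JlanModel(desk_model_config(len(li), len(vocab), seed))
            tc = TrainConfig(
                max_epochs=epochs, batch_size=16, shuffle_seed=seed,
                denoise=DenoiseConfig(enabled=enabled), patience=10**9,
            )
            best, record = train(model, tr, va, tc, noise_mask=nm)
            model.load_state_dict(best)
            f1 = evaluate(model, te).micro_f1
            if enabled:
                f1_denoise.append(f1)
                dropped = sum(record.dropped_total)
                hits = sum(record.noise_hits)
                overlap.append(hits / max(dropped, 1))
                # a uniform drop among positive entries hits noise at its base rate
                n_pos = sum(d.label_vector.sum() for d in tr)
                random_overlap.append(float(nm.sum()) / float(n_pos))
            else:
                f1_plain.append(f1)
    return {
        "denoise_micro_f1_mean": float(np.mean(f1_denoise)),
        "plain_micro_f1_mean": float(np.mean(f1_plain)),
        "denoise_micro_f1": [float(v) for v in f1_denoise],
        "plain_micro_f1": [float(v) for v in f1_plain],
        "drop_noise_overlap": float(np.mean(overlap)),
        "random_drop_overlap": float(np.mean(random_overlap)),
    }


def ablation_experiment(seeds=(0, 1, 2), corpus_seed: int = 11,
                        n_docs: int = 700, epochs: int = 100,
                        patience: int = 10**9,
                        modes=("full", "label_only", "self_only")) -> dict:
    """Attention ablation on a noiseless corpus: per-mode mean test metrics.

    Every mode gets the identical budget (``epochs`` epochs, no early stop)
    with model selection at the best validation micro-F1 epoch, so the
    comparison is a pure architecture contrast.
    """
    cfg = toy_corpus_config(corpus_seed, n_docs=n_docs)
    corpus = generate_corpus(cfg)
    n_tr, n_va = int(0.72 * n_docs), int(0.14 * n_docs)
    tr_raw = corpus.documents[:n_tr]
    enc_tr, vocab, li = encode_corpus(tr_raw)
    enc_va, _, _ = encode_corpus(corpus.documents[n_tr : n_tr + n_va], li, vocab=vocab)
    enc_te, _, _ = encode_corpus(corpus.documents[n_tr + n_va :], li, vocab=vocab)
    mc = desk_model_config(len(li), len(vocab), 0)
    tc = TrainConfig(
        max_epochs=epochs, batch_size=16,
        denoise=DenoiseConfig(enabled=False), patience=patience,
    )
    return run_ablation(enc_tr, enc_va, enc_te, mc, tc, modes, seeds)
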