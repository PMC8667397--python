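"""Synthetic multi-label corpora with the statistical structure of clinical
code prediction: a long-tailed (Zipfian) label prior, label-specific trigger
tokens embedded in Zipfian background text, and controllable annotation noise.

The generator exists so that every stage of the pipeline — preprocessing,
the dual-attention network, the truncation loss, the metrics — can be
exercised end to end at desk scale.  Each label owns a disjoint set of
``triggers_per_label`` trigger tokens; when a document carries the label,
each trigger appears independently with ``trigger_emission_rate``, placed at
uniform random positions among background tokens.  A document is therefore
identifiable from its text alone, which makes attention-recovery and
denoising experiments unambiguous.

Noise is injected on labels, not text (miscoding, not mistyping): in
``add_positive`` mode a corrupted document gains one spurious code with no
textual support; in ``swap_positive`` mode one true code is replaced.
The clean matrix, the noisy matrix and the flip mask are all returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import RawDocument, write_jsonl_corpus, write_label_file

NOISE_MODES = ("add_positive", "swap_positive")


@dataclass
class SyntheticConfig:
    L_labels: int = 20
    vocab_size: int = 500
    zipf_exponent: float = 1.2
    mean_labels_per_doc: float = 3.0
    triggers_per_label: int = 3
    trigger_emission_rate: float = 0.8
    doc_length_range: tuple[int, int] = (30, 60)
    noise_rate: float = 0.0
    noise_mode: str = "add_positive"
    n_docs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.L_labels < 2:
            raise ValueError("need at least 2 labels")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        n_trigger = self.L_labels * self.triggers_per_label
        if self.vocab_size <= n_trigger:
            raise ValueError(
                "vocab_size too small to allocate disjoint trigger sets "
                f"({n_trigger} triggers requested)"
            )


@dataclass
class SyntheticCorpus:
    documents: list[RawDocument]
    clean_labels: np.ndarray  # (N, L) binary
    noisy_labels: np.ndarray  # (N, L) binary
    noise_mask: np.ndarray  # (N, L) boolean, True where flipped
    trigger_tokens: dict[str, list[str]]  # code -> its trigger tokens
    codes: list[str]  # column order
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def descriptions(self) -> dict[str, str]:
        """Code descriptions = the label's trigger tokens (space-joined)."""
        return {c: " ".join(self.trigger_tokens[c]) for c in self.codes}

    def noisy_documents(self) -> list[RawDocument]:
        """Documents re-labelled with the noisy code sets."""
        out = []
        for i, d in enumerate(self.documents):
            codes = frozenset(
                self.codes[j] for j in np.flatnonzero(self.noisy_labels[i])
            )
            out.append(RawDocument(d.doc_id, d.text, codes))
        return out

    def write(self, outdir: str | Path) -> None:
        """Emit corpus.jsonl (noisy labels), labels.csv, noise_mask.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_jsonl_corpus(outdir / "corpus.jsonl", self.noisy_documents())
        write_jsonl_corpus(outdir / "corpus_clean.jsonl", self.documents)
        write_label_file(outdir / "labels.csv", self.descriptions)
        with open(outdir / "noise_mask.tsv", "w") as fh:
            fh.write("doc_id\tcode\n")
            for i, j in zip(*np.nonzero(self.noise_mask)):
                fh.write(f"{self.documents[i].doc_id}\t{self.codes[j]}\n")


def sample_label_prior(L_labels: int, s: float) -> np.ndarray:
    """Zipf prior p_i proportional to (i+1)^(-s), normalized, non-increasing."""
    if L_labels < 2:
        raise ValueError("need at least 2 labels")
    if s <= 0:
        raise ValueError("exponent must be positive")
    ranks = np.arange(1, L_labels + 1, dtype=np.float64)
    p = ranks**-s
    return p / p.sum()


def _truncated_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    """Poisson draw clipped into [lo, hi] (resampling, fall back to clip)."""
    for _ in range(100):
        v = int(rng.poisson(lam))
        if lo <= v <= hi:
            return v
    return int(np.clip(rng.poisson(lam), lo, hi))


def inject_noise(
    clean: np.ndarray, rho: float, mode: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt each document's code set independently with probability rho.

    ``add_positive``: one spurious code (uniform over the document's current
    negatives) is set.  ``swap_positive``: one true code is cleared and a
    random other code set.  Returns (noisy matrix, flip mask); the clean
    matrix is left untouched.
    """
    if mode not in NOISE_MODES:
        raise ValueError(f"unknown noise mode {mode!r}")
    rng = np.random.default_rng(seed)
    clean = np.asarray(clean)
    noisy = clean.copy()
    mask = np.zeros_like(clean, dtype=bool)
    for i in range(clean.shape[0]):
        if rng.random() >= rho:
            continue
        negatives = np.flatnonzero(clean[i] == 0)
        positives = np.flatnonzero(clean[i] == 1)
        if mode == "add_positive":
            if len(negatives) == 0:
                continue
            j = int(rng.choice(negatives))
            noisy[i, j] = 1
            mask[i, j] = True
        else:  # swap_positive
            if len(positives) == 0 or len(negatives) == 0:
                continue
            j_out = int(rng.choice(positives))
            j_in = int(rng.choice(negatives))
            noisy[i, j_out] = 0
            noisy[i, j_in] = 1
            mask[i, j_out] = True
            mask[i, j_in] = True
    return noisy, mask


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus; a pure function of (config, seed)."""
    rng = np.random.default_rng(config.seed)
    L = config.L_labels
    codes = [f"{i + 1:03d}" for i in range(L)]

    trigger_tokens = {
        codes[i]: [f"trig{i:03d}x{j}" for j in range(config.triggers_per_label)]
        for i in range(L)
    }
    n_background = config.vocab_size - L * config.triggers_per_label
    background = [f"w{i:04d}" for i in range(n_background)]
    bg_probs = sample_label_prior(n_background, config.zipf_exponent)

    prior = sample_label_prior(L, config.zipf_exponent)
    lo, hi = config.doc_length_range
    max_labels = min(L, 8)

    docs: list[RawDocument] = []
    clean = np.zeros((config.n_docs, L), dtype=np.int8)
    for i in range(config.n_docs):
        n_labels = _truncated_poisson(rng, config.mean_labels_per_doc, 1, max_labels)
        chosen = rng.choice(L, size=n_labels, replace=False, p=prior)
        clean[i, chosen] = 1
        length = int(rng.integers(lo, hi + 1))
        tokens = list(rng.choice(background, size=length, p=bg_probs))
        for j in chosen:
            for trig in trigger_tokens[codes[j]]:
                if rng.random() < config.trigger_emission_rate:
                    pos = int(rng.integers(0, len(tokens) + 1))
                    tokens.insert(pos, trig)
        docs.append(
            RawDocument(
                doc_id=f"doc{i:05d}",
                text=" ".join(tokens),
                codes=frozenset(codes[j] for j in chosen),
            )
        )

    noisy, mask = inject_noise(
        clean, config.noise_rate, config.noise_mode, seed=int(rng.integers(2**31))
    )
    return SyntheticCorpus(
        documents=docs,
        clean_labels=clean,
        noisy_labels=noisy,
        noise_mask=mask,
        trigger_tokens=trigger_tokens,
        codes=codes,
        config=config,
    )
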