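"""Corpus handling: tokenization, vocabulary, document/label encoding, embeddings.

The preprocessing mirrors the CAML-lineage pipeline used for discharge-summary
coding: lowercase, split on non-alphanumeric boundaries, drop tokens without an
alphabetic character, replace tokens seen in fewer than ``min_doc_freq``
training documents with UNK, and truncate documents to ``max_len`` tokens.

Word vectors come either from a small built-in skip-gram (negative sampling)
trainer or from a seeded random initialization; both are deterministic for a
fixed seed.  The PAD row is always zero and is never updated.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_ID = 0
UNK_ID = 1

_TOKEN_SPLIT = re.compile(r"[A-Za-z0-9]+")
_HAS_ALPHA = re.compile(r"[a-z]")


@dataclass(frozen=True)
class RawDocument:
    """A clinical note with its assigned code set."""

    doc_id: str
    text: str
    codes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "codes", frozenset(self.codes))


def tokenize(text: str) -> list[str]:
    """Lowercase, split on alphanumeric runs, keep tokens with >=1 a-z letter.

    Purely numeric tokens ("3", "120") are deleted; mixed tokens ("x2",
    "covid19") survive because they contain alphabetic characters.
    """
    tokens = _TOKEN_SPLIT.findall(text.lower())
    return [t for t in tokens if _HAS_ALPHA.search(t)]


@dataclass
class Vocabulary:
    """Token <-> id maps with document-frequency counts.

    ids are contiguous from 0 with PAD=0 and UNK=1 fixed.
    """

    token_to_id: dict[str, int]
    doc_freq: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def encode(self, tokens: Iterable[str]) -> list[int]:
        get = self.token_to_id.get
        return [get(t, UNK_ID) for t in tokens]

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.id_to_token[i] for i in ids]

    def to_dict(self) -> dict:
        return {"token_to_id": self.token_to_id, "doc_freq": self.doc_freq}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Vocabulary":
        return cls(dict(d["token_to_id"]), dict(d.get("doc_freq", {})))


def build_vocabulary(
    tokenized_docs: Sequence[Sequence[str]], min_doc_freq: int = 2
) -> Vocabulary:
    """Keep a token iff it appears in at least ``min_doc_freq`` training docs."""
    df: Counter[str] = Counter()
    for toks in tokenized_docs:
        df.update(set(toks))
    kept = sorted(t for t, c in df.items() if c >= min_doc_freq)
    token_to_id = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    for t in kept:
        token_to_id[t] = len(token_to_id)
    return Vocabulary(token_to_id, dict(df))


@dataclass(frozen=True)
class EncodedDocument:
    doc_id: str
    token_ids: np.ndarray  # int array, length n <= max_len
    label_vector: np.ndarray  # binary, length L_labels

    @property
    def n(self) -> int:
        return int(self.token_ids.shape[0])


def encode_document(
    doc_id: str,
    tokens: Sequence[str],
    codes: Iterable[str],
    vocab: Vocabulary,
    label_index: Mapping[str, int],
    max_len: int = 2500,
) -> EncodedDocument:
    """Map tokens to ids (UNK for out-of-vocabulary), truncate, binarize codes."""
    ids = np.asarray(vocab.encode(tokens[:max_len]), dtype=np.int64)
    y = np.zeros(len(label_index), dtype=np.int8)
    for code in codes:
        if code not in label_index:
            raise KeyError(f"code {code!r} is not in the label vocabulary")
        y[label_index[code]] = 1
    return EncodedDocument(doc_id, ids, y)


@dataclass(frozen=True)
class CodeDescription:
    code: str
    description_token_ids: np.ndarray


def encode_code_descriptions(
    descriptions: Mapping[str, str], vocab: Vocabulary
) -> list[CodeDescription]:
    """Tokenize each code's free-text description into the model vocabulary.

    Descriptions are tokenized with the same rules as note text but are not
    subject to the document-frequency filter.
    """
    out = []
    for code in sorted(descriptions):
        ids = np.asarray(vocab.encode(tokenize(descriptions[code])), dtype=np.int64)
        out.append(CodeDescription(code, ids))
    return out


# ---------------------------------------------------------------------------
# word vectors


def random_embeddings(
    vocab_size: int, e_dim: int = 256, seed: int = 0, scale: float = 0.1
) -> np.ndarray:
    """Seeded Gaussian init N(0, scale^2); PAD row zeroed."""
    if e_dim <= 0:
        raise ValueError("e_dim must be positive")
    rng = np.random.default_rng(seed)
    E = rng.normal(0.0, scale, size=(vocab_size, e_dim))
    E[PAD_ID] = 0.0
    return E


def pretrain_embeddings(
    tokenized_docs: Sequence[Sequence[str]],
    vocab: Vocabulary,
    e_dim: int = 256,
    seed: int = 0,
    window: int = 4,
    negatives: int = 4,
    epochs: int = 3,
    lr: float = 0.05,
) -> np.ndarray:
    """Skip-gram with negative sampling over the training corpus.

    A compact single-worker implementation: for each (center, context) pair
    within ``window``, the center vector is pushed toward the context output
    vector and away from ``negatives`` sampled output vectors (unigram^0.75
    noise distribution).  Deterministic for a fixed seed.  Returns the input
    (center) vectors with the PAD row zeroed.
    """
    if e_dim <= 0:
        raise ValueError("e_dim must be positive")
    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = rng.uniform(-0.5 / e_dim, 0.5 / e_dim, size=(V, e_dim))
    W_out = np.zeros((V, e_dim))

    counts = np.zeros(V)
    encoded = []
    for toks in tokenized_docs:
        ids = [i for i in vocab.encode(toks) if i != PAD_ID]
        encoded.append(ids)
        for i in ids:
            counts[i] += 1
    noise = counts**0.75
    noise[PAD_ID] = 0.0
    if noise.sum() == 0:
        E = random_embeddings(V, e_dim, seed)
        return E
    noise /= noise.sum()

    for _ in range(epochs):
        for ids in encoded:
            n = len(ids)
            for pos, center in enumerate(ids):
                lo = max(0, pos - window)
                hi = min(n, pos + window + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    targets = [ids[ctx_pos]] + list(
                        rng.choice(V, size=negatives, p=noise)
                    )
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    vc = W_in[center]
                    out = W_out[targets]
                    p = 1.0 / (1.0 + np.exp(-(out @ vc)))
                    gout = np.outer(p - labels, vc)
                    gin = (p - labels) @ out
                    W_out[targets] -= lr * gout
                    W_in[center] -= lr * gin
    W_in[PAD_ID] = 0.0
    return W_in


def save_embeddings_text(path: str | Path, vocab: Vocabulary, E: np.ndarray) -> None:
    """word2vec text format: header line, then `token v1 ... v_e` per line."""
    with open(path, "w") as fh:
        fh.write(f"{E.shape[0]} {E.shape[1]}\n")
        for i in range(E.shape[0]):
            vals = " ".join(f"{v:.6g}" for v in E[i])
            fh.write(f"{vocab.id_to_token[i]} {vals}\n")


def load_embeddings_text(path: str | Path, vocab: Vocabulary) -> np.ndarray:
    with open(path) as fh:
        n, e_dim = map(int, fh.readline().split())
        E = np.zeros((len(vocab), e_dim))
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            token = parts[0]
            if token in vocab:
                E[vocab.token_to_id[token]] = [float(v) for v in parts[1:]]
    E[PAD_ID] = 0.0
    return E


# ---------------------------------------------------------------------------
# file formats


def read_jsonl_corpus(path: str | Path) -> list[RawDocument]:
    """JSON-lines corpus: one object per line with doc_id, text, codes."""
    docs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            docs.append(RawDocument(obj["doc_id"], obj["text"], frozenset(obj["codes"])))
    return docs


def write_jsonl_corpus(path: str | Path, docs: Iterable[RawDocument]) -> None:
    with open(path, "w") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "text": d.text, "codes": sorted(d.codes)}
                )
                + "\n"
            )


def read_label_file(path: str | Path) -> dict[str, str]:
    """CSV with columns code,description -> ordered code->description map."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["code"]] = row.get("description", "") or ""
    return out


def write_label_file(path: str | Path, descriptions: Mapping[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "description"])
        for code in sorted(descriptions):
            w.writerow([code, descriptions[code]])


def label_index_from_codes(codes: Iterable[str]) -> dict[str, int]:
    """Stable code->column map (sorted order)."""
    return {c: i for i, c in enumerate(sorted(set(codes)))}
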