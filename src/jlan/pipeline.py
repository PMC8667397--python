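"""Convenience glue: raw corpus -> encoded documents ready for the model."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import (
    EncodedDocument,
    RawDocument,
    Vocabulary,
    build_vocabulary,
    encode_document,
    label_index_from_codes,
    tokenize,
)


def encode_corpus(
    docs: Sequence[RawDocument],
    label_index: Mapping[str, int] | None = None,
    vocab: Vocabulary | None = None,
    min_doc_freq: int = 2,
    max_len: int = 2500,
) -> tuple[list[EncodedDocument], Vocabulary, dict[str, int]]:
    """Tokenize, build/reuse the vocabulary, and encode every document.

    When ``vocab`` is None it is built from these documents (treat them as the
    training split); pass the training vocabulary when encoding held-out
    splits so UNK behaves correctly.
    """
    tokenized = [tokenize(d.text) for d in docs]
    if vocab is None:
        vocab = build_vocabulary(tokenized, min_doc_freq=min_doc_freq)
    if label_index is None:
        all_codes = set()
        for d in docs:
            all_codes |= d.codes
        label_index = label_index_from_codes(all_codes)
    encoded = [
        encode_document(d.doc_id, toks, d.codes, vocab, label_index, max_len=max_len)
        for d, toks in zip(docs, tokenized)
    ]
    return encoded, vocab, dict(label_index)


def unk_rate(encoded: Iterable[EncodedDocument]) -> float:
    """Fraction of token ids mapped to UNK (reported for held-out splits)."""
    from .corpus import UNK_ID

    total = 0
    unk = 0
    for d in encoded:
        total += d.n
        unk += int((d.token_ids == UNK_ID).sum())
    return unk / total if total else 0.0
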