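"""Label encoding and embedding of token lists.

Token lists become fixed-length integer label vectors (drug maximum 50,
protein maximum 545 by default; longer sequences keep their prefix) and
are then embedded either by a learned token table plus a learned
positional table (summed, hidden size 384 by default) or by one-hot
indicator rows whose width is the vocabulary size. Padding uses label 0
and padded rows are tracked by a mask so the attention stage can exclude
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Parameter, Tensor, add, embedding
from .tokenization import PAD_LABEL, TokenVocabulary

#: Default maximum token positions (drug, protein) and hidden size.
MAX_LEN_DRUG = 50
MAX_LEN_PROTEIN = 545
HIDDEN_SIZE = 384


@dataclass
class LabelVector:
    """A fixed-length right-padded integer encoding of one sequence."""

    labels: np.ndarray  # shape (max_len,), int32
    true_len: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if (self.labels[self.true_len:] != PAD_LABEL).any():
            raise ValueError("positions past true_len must hold PAD")

    @property
    def mask(self) -> np.ndarray:
        """Boolean flags marking real (non-PAD) positions."""
        out = np.zeros(self.labels.shape[0], dtype=bool)
        out[: self.true_len] = True
        return out


def label_encode(tokens: list[str], vocab: TokenVocabulary,
                 max_len: int) -> LabelVector:
    """Map tokens to labels, truncating to or right-padding at max_len."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    labels = np.full(max_len, PAD_LABEL, dtype=np.int32)
    kept = tokens[:max_len]
    for i, t in enumerate(kept):
        labels[i] = vocab.label(t)
    return LabelVector(labels=labels, true_len=len(kept))


@dataclass
class EmbeddingMatrix:
    """A token-position x feature matrix with a PAD-row mask."""

    values: Tensor
    mask: np.ndarray

    @property
    def shape(self):
        return self.values.shape


def embed_learned(lv: LabelVector, token_table: Tensor,
                  pos_table: Tensor) -> EmbeddingMatrix:
    """Sum token-table and position-table rows: row i =
    token_table[labels[i]] + pos_table[i]."""
    n = lv.labels.shape[0]
    if lv.labels.max(initial=0) >= token_table.shape[0]:
        raise ValueError("label out of token-table range")
    if pos_table.shape[0] < n:
        raise ValueError("positional table shorter than sequence")
    tok = embedding(token_table, lv.labels)
    pos = embedding(pos_table, np.arange(n))
    return EmbeddingMatrix(values=add(tok, pos), mask=lv.mask)


def embed_onehot(lv: LabelVector, vocab: TokenVocabulary) -> EmbeddingMatrix:
    """Indicator-row embedding; PAD rows are all-zero; width = label count."""
    width = vocab.n_labels
    mat = np.zeros((lv.labels.shape[0], width), dtype=np.float32)
    for i in range(lv.true_len):
        mat[i, lv.labels[i]] = 1.0
    return EmbeddingMatrix(values=Tensor(mat), mask=lv.mask)


def make_embedding_tables(n_labels: int, max_len: int,
                          hidden: int = HIDDEN_SIZE,
                          rng: np.random.Generator | None = None
                          ) -> tuple[Parameter, Parameter]:
    """Initialise learnable token and positional tables ~ N(0, 1)."""
    rng = rng or np.random.default_rng()
    tok = Parameter(rng.standard_normal((n_labels, hidden)))
    pos = Parameter(rng.standard_normal((max_len, hidden)))
    return tok, pos
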