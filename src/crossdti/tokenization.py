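"""Sequence tokenization and frequent-consecutive-subsequence (FCS) mining.

Drugs arrive as SMILES strings and proteins as amino-acid letter strings.
Both can be consumed at single-character resolution, as SELFIES words
(drugs only), or re-segmented into variable-length sub-sequences by FCS
mining — a BPE-style procedure that repeatedly fuses the most frequent
adjacent token pair across a training corpus until no pair reaches a
frequency threshold or the vocabulary hits a size cap.

SMILES "characters" here are strictly single characters (a letter or a
symbol), so two-letter atoms such as Cl split into ``C`` and ``l``; the
tokens are learning units, not chemical entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

PAD_LABEL = 0
UNK_LABEL = 1
UNK_TOKEN = "<unk>"

#: The 20 standard amino acids.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

ALPHABET_KINDS = ("smiles_char", "selfies_word", "aa_letter",
                  "fcs_drug", "fcs_protein")


@dataclass
class TokenVocabulary:
    """An ordered token set with integer labels and (optional) merge rules.

    Labels are contiguous positive integers starting at 2; 0 is reserved
    for padding and 1 for unknown base symbols. For mined (FCS)
    vocabularies, ``merges`` records the fused pairs in mining order, and
    every merged token is the concatenation of its pair.
    """

    tokens: list[str]
    alphabet_kind: str
    merges: list[tuple[str, str]] = field(default_factory=list)
    label_of: dict[str, int] = field(init=False)

    def __post_init__(self):
        if self.alphabet_kind not in ALPHABET_KINDS:
            raise ValueError(f"unknown alphabet_kind {self.alphabet_kind!r}")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for a, b in self.merges:
            if a + b not in self.tokens:
                raise ValueError(f"merged token {a + b!r} missing")
        self.label_of = {t: i + 2 for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_labels(self) -> int:
        """Total label count including PAD and UNK."""
        return len(self.tokens) + 2

    def label(self, token: str) -> int:
        return self.label_of.get(token, UNK_LABEL)

    # -- serialization (plain text) ------------------------------------
    def save(self, path: str | Path) -> None:
        lines = [f"#alphabet_kind\t{self.alphabet_kind}", "#tokens"]
        lines += [f"{t}\t{self.label_of[t]}" for t in self.tokens]
        lines.append("#merges")
        lines += [f"{a}\t{b}" for a, b in self.merges]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        kind, tokens, merges = None, [], []
        section = None
        for raw in Path(path).read_text().splitlines():
            if raw.startswith("#alphabet_kind"):
                kind = raw.split("\t", 1)[1]
            elif raw == "#tokens":
                section = "tokens"
            elif raw == "#merges":
                section = "merges"
            elif raw and section == "tokens":
                tokens.append(raw.split("\t")[0])
            elif raw and section == "merges":
                a, b = raw.split("\t")
                merges.append((a, b))
        if kind is None:
            raise ValueError(f"malformed vocabulary file {path}")
        return cls(tokens=tokens, alphabet_kind=kind, merges=merges)


@dataclass
class Corpus:
    """A training collection of drug or protein sequences."""

    sequences: list[str]
    kind: str  # "drug" | "protein"

    def __post_init__(self):
        if self.kind not in ("drug", "protein"):
            raise ValueError("kind must be 'drug' or 'protein'")
        if not self.sequences:
            raise ValueError("empty corpus")


# -- base tokenizers ----------------------------------------------------

def tokenize_smiles_chars(smiles: str) -> list[str]:
    """Split a SMILES string into single characters, e.g. CN=C=O ->
    [C, N, =, C, =, O]."""
    if not smiles:
        raise ValueError("empty sequence")
    return list(smiles)


def tokenize_protein(seq: str) -> list[str]:
    """Split an AA sequence into letters; non-standard letters map to UNK."""
    if not seq:
        raise ValueError("empty sequence")
    return [c if c in STANDARD_AA else UNK_TOKEN for c in seq]


def tokenize_selfies(smiles: str) -> list[str]:
    """Translate a SMILES string to its SELFIES word list."""
    from . import selfies_codec

    return selfies_codec.encode_selfies(smiles)


def base_tokenize(seq: str, kind: str) -> list[str]:
    return tokenize_protein(seq) if kind == "protein" else tokenize_smiles_chars(seq)


# -- FCS mining ---------------------------------------------------------

def _pair_counts(seqs: list[list[str]]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for toks in seqs:
        for pair in zip(toks, toks[1:]):
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def _merge_seq(toks: list[str], pair: tuple[str, str]) -> list[str]:
    """Fuse every (non-overlapping, left-to-right) occurrence of `pair`."""
    a, b = pair
    out: list[str] = []
    i = 0
    n = len(toks)
    while i < n:
        if i + 1 < n and toks[i] == a and toks[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(toks[i])
            i += 1
    return out


def mine_fcs(corpus: Corpus, min_freq: int = 5,
             max_vocab: int | None = None) -> TokenVocabulary:
    """Mine an FCS vocabulary from a corpus by iterative pair fusion.

    Each round counts all adjacent token pairs across the working corpus,
    fuses the most frequent pair into a single token, and repeats until
    the best pair's frequency drops below ``min_freq`` or the vocabulary
    reaches ``max_vocab`` tokens. Frequency ties break by lexicographic
    order of the concatenated token, which makes mining deterministic.

    Parameters
    ----------
    min_freq : minimum corpus frequency for a pair to be fused (>= 2).
    max_vocab : vocabulary size cap; defaults to 2,000 for drug corpora
        and 10,000 for protein corpora.
    """
    if min_freq < 2:
        raise ValueError("min_freq must be >= 2")
    if max_vocab is None:
        max_vocab = 2000 if corpus.kind == "drug" else 10000
    seqs = [base_tokenize(s, corpus.kind) for s in corpus.sequences]
    alphabet = sorted({t for toks in seqs for t in toks if t != UNK_TOKEN})
    if max_vocab <= len(alphabet):
        raise ValueError("max_vocab must exceed the base alphabet size")

    tokens = list(alphabet)
    merges: list[tuple[str, str]] = []
    # seq index per pair lets each round's fusion touch only the
    # sequences that actually contain the winning pair
    counts = _pair_counts(seqs)
    containing: dict[tuple[str, str], set[int]] = {}
    for i, toks in enumerate(seqs):
        for pair in zip(toks, toks[1:]):
            containing.setdefault(pair, set()).add(i)

    while len(tokens) < max_vocab and counts:
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0][0] + kv[0][1]))
        (a, b), freq = best
        if freq < min_freq:
            break
        merges.append((a, b))
        tokens.append(a + b)
        for i in sorted(containing.get((a, b), ())):
            old = seqs[i]
            new = _merge_seq(old, (a, b))
            if new == old:
                continue
            for pair in zip(old, old[1:]):
                counts[pair] -= 1
                if counts[pair] == 0:
                    del counts[pair]
                    containing.pop(pair, None)
            for pair in zip(new, new[1:]):
                counts[pair] = counts.get(pair, 0) + 1
                containing.setdefault(pair, set()).add(i)
            seqs[i] = new
        counts.pop((a, b), None)
        containing.pop((a, b), None)

    kind = "fcs_drug" if corpus.kind == "drug" else "fcs_protein"
    return TokenVocabulary(tokens=tokens, alphabet_kind=kind, merges=merges)


def segment_with_vocab(base_tokens: list[str],
                       vocab: TokenVocabulary) -> list[str]:
    """Re-segment base tokens with a mined vocabulary.

    Applies the vocabulary's merges by always fusing the earliest-mined
    applicable pair first, which is equivalent to replaying the merge
    list in mining order. The concatenation of the output equals the
    concatenation of the input.
    """
    if not vocab.merges:
        return list(base_tokens)
    rank = {pair: i for i, pair in enumerate(vocab.merges)}
    toks = list(base_tokens)
    while len(toks) > 1:
        pairs = set(zip(toks, toks[1:]))
        candidates = [p for p in pairs if p in rank]
        if not candidates:
            break
        best = min(candidates, key=rank.__getitem__)
        toks = _merge_seq(toks, best)
    return toks


def segment_replay(base_tokens: list[str],
                   vocab: TokenVocabulary) -> list[str]:
    """Reference segmentation: replay merges strictly in mining order."""
    toks = list(base_tokens)
    for pair in vocab.merges:
        toks = _merge_seq(toks, pair)
    return toks


def char_vocabulary(corpus: Corpus) -> TokenVocabulary:
    """Single-character (or AA-letter) vocabulary from a corpus."""
    alphabet = sorted({
        t for s in corpus.sequences
        for t in base_tokenize(s, corpus.kind) if t != UNK_TOKEN
    })
    kind = "smiles_char" if corpus.kind == "drug" else "aa_letter"
    return TokenVocabulary(tokens=alphabet, alphabet_kind=kind)


def selfies_vocabulary(smiles_list: list[str]) -> TokenVocabulary:
    """SELFIES word vocabulary from a drug corpus (unconvertible skipped)."""
    from . import selfies_codec

    words: set[str] = set()
    for s in smiles_list:
        try:
            words.update(selfies_codec.encode_selfies(s))
        except ValueError:
            continue
    if not words:
        raise ValueError("no convertible SMILES in corpus")
    return TokenVocabulary(tokens=sorted(words), alphabet_kind="selfies_word")


def token_spans(tokens: list[str]) -> list[tuple[int, int]]:
    """Half-open [start, end) character spans covered by each token."""
    spans = []
    pos = 0
    for t in tokens:
        width = 1 if t == UNK_TOKEN else len(t)
        spans.append((pos, pos + width))
        pos += width
    return spans
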