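"""DTI datasets: samples, splitting, balancing, and delimited-text IO.

A sample is a (drug SMILES, protein sequence, binary label) triple,
optionally annotated with experimentally determined binding residues
(1-based positions on the protein). Positive pairs are divided into
training, validation and test sets at a 7:1:2 ratio; training negatives
are downsampled to match the training positives, and the remaining
negatives go to validation and test (in 1:2 proportion), which leaves
the test set with whatever class skew the source data carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPLITS = ("train", "valid", "test")


@dataclass(frozen=True)
class DTISample:
    """One labeled drug-protein pair."""

    drug_smiles: str
    protein_seq: str
    label: int
    protein_id: str | None = None
    binding_sites: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        bad = [p for p in self.binding_sites
               if not 1 <= p <= len(self.protein_seq)]
        if bad:
            raise ValueError(f"binding sites outside protein: {bad}")


@dataclass
class DTIDataset:
    """Samples with disjoint train/valid/test split assignments."""

    samples: list[DTISample]
    split_of: list[str]

    def __post_init__(self):
        if len(self.samples) != len(self.split_of):
            raise ValueError("split tags must align with samples")
        bad = set(self.split_of) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split tags {bad}")

    def subset(self, split: str) -> list[DTISample]:
        return [s for s, t in zip(self.samples, self.split_of) if t == split]

    def counts(self) -> dict[str, dict[int, int]]:
        out: dict[str, dict[int, int]] = {s: {0: 0, 1: 0} for s in SPLITS}
        for s, t in zip(self.samples, self.split_of):
            out[t][s.label] += 1
        return out


def split_dataset(samples: list[DTISample], ratios=(7, 1, 2),
                  seed: int = 0) -> DTIDataset:
    """Split positives 7:1:2 and balance training negatives.

    Positive counts for validation and test are floored fractions of the
    positive total; the remainder stays in training. Training negatives
    are downsampled (without replacement) to equal the training
    positives; remaining negatives are divided between validation and
    test in the validation:test ratio.
    """
    rng = np.random.default_rng(seed)
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos:
        raise ValueError("no positive samples")
    total = sum(ratios)
    rng.shuffle(pos)
    rng.shuffle(neg)

    n_valid = int(len(pos) * ratios[1] / total)
    n_test = int(len(pos) * ratios[2] / total)
    pos_valid, pos_test = pos[:n_valid], pos[n_valid:n_valid + n_test]
    pos_train = pos[n_valid + n_test:]

    n_neg_train = min(len(pos_train), len(neg))
    neg_train, rest = neg[:n_neg_train], neg[n_neg_train:]
    n_neg_valid = int(round(len(rest) * ratios[1] / (ratios[1] + ratios[2])))
    neg_valid, neg_test = rest[:n_neg_valid], rest[n_neg_valid:]

    samples_out, tags = [], []
    for group, tag in ((pos_train, "train"), (pos_valid, "valid"),
                       (pos_test, "test"), (neg_train, "train"),
                       (neg_valid, "valid"), (neg_test, "test")):
        samples_out.extend(group)
        tags.extend([tag] * len(group))
    return DTIDataset(samples=samples_out, split_of=tags)


def filter_invalid_smiles(samples: list[DTISample]) -> list[DTISample]:
    """Drop samples whose SMILES fails RDKit parsing; log the count."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    kept = [s for s in samples
            if Chem.MolFromSmiles(s.drug_smiles) is not None]
    dropped = len(samples) - len(kept)
    if dropped:
        logger.info("filter_invalid_smiles: dropped %d of %d samples",
                    dropped, len(samples))
    return kept


# -- delimited-text IO --------------------------------------------------

def read_dti_table(path: str | Path,
                   annotations: dict[str, frozenset[int]] | None = None,
                   fasta: dict[str, str] | None = None) -> list[DTISample]:
    """Read a DTI table (columns smiles, sequence, label; optional
    protein_id), tab- or comma-separated, auto-detected.

    When ``fasta`` maps protein ids to sequences, the sequence column
    may be omitted and is joined on protein_id instead.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"smiles", "label"}
    if fasta is None:
        required.add("sequence")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)} in {path}")
    has_seq = "sequence" in df.columns
    out = []
    for row in df.itertuples(index=False):
        pid = str(row.protein_id) if "protein_id" in df.columns else None
        seq = str(row.sequence) if has_seq else ""
        if (not seq or seq == "nan") and fasta is not None:
            if pid is None or pid not in fasta:
                raise ValueError(f"no FASTA sequence for protein {pid!r}")
            seq = fasta[pid]
        sites = frozenset()
        if annotations and pid is not None:
            sites = annotations.get(pid, frozenset())
        out.append(DTISample(drug_smiles=str(row.smiles), protein_seq=seq,
                             label=int(row.label), protein_id=pid,
                             binding_sites=sites))
    return out


def write_dti_table(samples: list[DTISample], path: str | Path,
                    sep: str = "\t") -> None:
    rows = [{"smiles": s.drug_smiles, "sequence": s.protein_seq,
             "label": s.label, "protein_id": s.protein_id or ""}
            for s in samples]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_binding_sites(path: str | Path) -> dict[str, frozenset[int]]:
    """Read annotations: lines of `protein_id<TAB>pos1,pos2,...` (1-based)."""
    out: dict[str, frozenset[int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        pid, _, rest = line.partition("\t")
        positions = frozenset(int(x) for x in rest.split(",") if x.strip())
        if any(p < 1 for p in positions):
            raise ValueError(f"binding positions must be 1-based: {line!r}")
        out[pid] = positions
    return out


def write_binding_sites(annotations: dict[str, frozenset[int]],
                        path: str | Path) -> None:
    lines = [f"{pid}\t{','.join(str(p) for p in sorted(sites))}"
             for pid, sites in annotations.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by FASTA record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
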