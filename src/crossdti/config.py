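"""Run configuration: one YAML-serializable record of every knob.

Defaults are the reference configuration: 4 attention heads, hidden
size 384, learning rate 0.001, 50 epochs, batch 128, drug/protein
position caps 50/545, decision threshold 0.5, top-k 30, 10,000
permutation iterations, 5 evaluation runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    architecture: str = "CA_P"
    scheme: str = "fcs"
    max_len_drug: int = 50
    max_len_protein: int = 545
    hidden_size: int = 384
    n_heads: int = 4
    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 128
    threshold: float = 0.5
    top_k: int = 30
    iterations: int = 10000
    n_runs: int = 5
    seed: int = 0
    min_freq: int = 5
    max_vocab_drug: int = 2000
    max_vocab_protein: int = 10000
    validation_fraction: float = 0.125
    paths: dict = field(default_factory=dict)

    def estimator_params(self) -> dict:
        """Keyword arguments for DTIClassifier."""
        return {
            "architecture": self.architecture, "scheme": self.scheme,
            "max_len_drug": self.max_len_drug,
            "max_len_protein": self.max_len_protein,
            "hidden_size": self.hidden_size, "n_heads": self.n_heads,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs, "batch_size": self.batch_size,
            "threshold": self.threshold, "min_freq": self.min_freq,
            "max_vocab_drug": self.max_vocab_drug,
            "max_vocab_protein": self.max_vocab_protein,
            "validation_fraction": self.validation_fraction,
            "random_state": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self),
                                             sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)
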