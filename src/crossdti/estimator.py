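"""Scikit-learn style estimator for cross-attention DTI prediction.

``DTIClassifier`` is a binary classifier over (SMILES, protein
sequence) pairs. ``fit`` mines the token vocabularies on the training
data, trains the configured attention architecture with Adam on binary
cross-entropy, and keeps the parameters of the epoch with the best
validation PRAUC. It composes with sklearn model selection
(get_params/set_params, predict_proba, classes_).

Defaults follow the reference configuration: 4 attention heads, hidden
size 384, learning rate 0.001, batch size 128, up to 50 epochs, drug /
protein position caps 50 / 545.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, bce_with_logits
from . import tokenization as tok
from .encoding import label_encode
from .interpret import ExpandedAttentionMap, expand_attention
from .metrics import MetricSet, average_metrics, evaluate_scores
from .model import DTIModel, ModelConfig

#: Encoding schemes: (drug token kind, embedding kind).
SCHEMES = ("fcs", "smiles", "selfies", "onehot_smiles", "onehot_selfies")


class SequenceEncoder:
    """Maps raw sequence pairs to padded label matrices for one scheme."""

    def __init__(self, scheme: str, max_len_drug: int, max_len_protein: int,
                 min_freq: int = 5, max_vocab_drug: int = 2000,
                 max_vocab_protein: int = 10000):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
        self.scheme = scheme
        self.max_len_drug = max_len_drug
        self.max_len_protein = max_len_protein
        self.min_freq = min_freq
        self.max_vocab_drug = max_vocab_drug
        self.max_vocab_protein = max_vocab_protein
        self._drug_cache: dict[str, list[str]] = {}
        self._protein_cache: dict[str, list[str]] = {}

    @property
    def embedding_kind(self) -> str:
        return "onehot" if self.scheme.startswith("onehot") else "learned"

    def fit(self, drugs: list[str], proteins: list[str]) -> "SequenceEncoder":
        if self.scheme == "fcs":
            self.drug_vocab_ = tok.mine_fcs(
                tok.Corpus(list(drugs), "drug"), self.min_freq,
                self.max_vocab_drug)
            self.protein_vocab_ = tok.mine_fcs(
                tok.Corpus(list(proteins), "protein"), self.min_freq,
                self.max_vocab_protein)
        else:
            if self.scheme.endswith("selfies"):
                self.drug_vocab_ = tok.selfies_vocabulary(list(drugs))
            else:
                self.drug_vocab_ = tok.char_vocabulary(
                    tok.Corpus(list(drugs), "drug"))
            self.protein_vocab_ = tok.char_vocabulary(
                tok.Corpus(list(proteins), "protein"))
        return self

    def drug_tokens(self, smiles: str) -> list[str]:
        if smiles not in self._drug_cache:
            if self.scheme.endswith("selfies"):
                toks = tok.tokenize_selfies(smiles)
            else:
                toks = tok.tokenize_smiles_chars(smiles)
                if self.scheme == "fcs":
                    toks = tok.segment_with_vocab(toks, self.drug_vocab_)
            self._drug_cache[smiles] = toks
        return self._drug_cache[smiles]

    def protein_tokens(self, seq: str) -> list[str]:
        if seq not in self._protein_cache:
            toks = tok.tokenize_protein(seq)
            if self.scheme == "fcs":
                toks = tok.segment_with_vocab(toks, self.protein_vocab_)
            self._protein_cache[seq] = toks
        return self._protein_cache[seq]

    def encode(self, drugs: list[str], proteins: list[str]
               ) -> tuple[np.ndarray, np.ndarray]:
        ld = np.stack([label_encode(self.drug_tokens(s), self.drug_vocab_,
                                    self.max_len_drug).labels
                       for s in drugs])
        lp = np.stack([label_encode(self.protein_tokens(s),
                                    self.protein_vocab_,
                                    self.max_len_protein).labels
                       for s in proteins])
        return ld, lp

    def spans(self, smiles: str, protein: str
              ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Token spans of the encoded (possibly truncated) pair, in base
        units (characters for drugs/proteins; words for SELFIES)."""
        dt = self.drug_tokens(smiles)[: self.max_len_drug]
        pt = self.protein_tokens(protein)[: self.max_len_protein]
        if self.scheme.endswith("selfies"):
            drug_spans = [(i, i + 1) for i in range(len(dt))]
        else:
            drug_spans = tok.token_spans(dt)
        return drug_spans, tok.token_spans(pt)


def _unpack_X(X) -> tuple[list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = {c.lower(): c for c in X.columns}
        if "smiles" in cols and "sequence" in cols:
            return (X[cols["smiles"]].astype(str).tolist(),
                    X[cols["sequence"]].astype(str).tolist())
        X = X.to_numpy()
    arr = np.asarray(X, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("X must be (n_samples, 2): SMILES, protein "
                         "sequence")
    return [str(v) for v in arr[:, 0]], [str(v) for v in arr[:, 1]]


class DTIClassifier(ClassifierMixin, BaseEstimator):
    """Cross-attention drug-target interaction classifier.

    Parameters mirror the reference configuration; see the module
    docstring. ``architecture`` is one of CA_DP, CA2_DP, CA3_DP,
    CA_DP_FCL, SA_DP, CA_D, CA_P (default CA_P: protein context decoded
    by a CNN). ``scheme`` selects the token/embedding combination: fcs,
    smiles, selfies, onehot_smiles, onehot_selfies.
    """

    def __init__(self, architecture: str = "CA_P", scheme: str = "fcs",
                 max_len_drug: int = 50, max_len_protein: int = 545,
                 hidden_size: int = 384, n_heads: int = 4,
                 learning_rate: float = 1e-3, max_epochs: int = 50,
                 batch_size: int = 128, validation_fraction: float = 0.125,
                 threshold: float = 0.5, min_freq: int = 5,
                 max_vocab_drug: int = 2000, max_vocab_protein: int = 10000,
                 dropout: float = 0.1, mask_pad: bool = True,
                 scale_mode: str = "sqrt", positional: bool | None = None,
                 random_state: int | None = None, verbose: bool = False):
        self.architecture = architecture
        self.scheme = scheme
        self.max_len_drug = max_len_drug
        self.max_len_protein = max_len_protein
        self.hidden_size = hidden_size
        self.n_heads = n_heads
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.min_freq = min_freq
        self.max_vocab_drug = max_vocab_drug
        self.max_vocab_protein = max_vocab_protein
        self.dropout = dropout
        self.mask_pad = mask_pad
        self.scale_mode = scale_mode
        self.positional = positional
        self.random_state = random_state
        self.verbose = verbose

    # -- fitting --------------------------------------------------------
    def fit(self, X, y, validation_data=None) -> "DTIClassifier":
        drugs, proteins = _unpack_X(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(drugs) != len(y) or len(drugs) == 0:
            raise ValueError("X and y must be non-empty and aligned")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2

        seed = 0 if self.random_state is None else int(self.random_state)
        rng_init = np.random.default_rng(seed)
        rng_drop = np.random.default_rng(seed + 1_000_003)
        rng_shuffle = np.random.default_rng(seed + 2_000_003)

        if validation_data is not None:
            Xv, yv = validation_data
            vd, vp = _unpack_X(Xv)
            yv = np.asarray(yv).astype(int)
            td, tp, ty = drugs, proteins, y
        elif self.validation_fraction > 0 and len(drugs) >= 8:
            idx_tr, idx_va = train_test_split(
                np.arange(len(drugs)), test_size=self.validation_fraction,
                random_state=seed, stratify=y)
            td = [drugs[i] for i in idx_tr]
            tp = [proteins[i] for i in idx_tr]
            ty = y[idx_tr]
            vd = [drugs[i] for i in idx_va]
            vp = [proteins[i] for i in idx_va]
            yv = y[idx_va]
        else:
            td, tp, ty = drugs, proteins, y
            vd = vp = yv = None

        self.encoder_ = SequenceEncoder(
            self.scheme, self.max_len_drug, self.max_len_protein,
            self.min_freq, self.max_vocab_drug, self.max_vocab_protein)
        self.encoder_.fit(td, tp)

        Xd, Xp = self.encoder_.encode(td, tp)
        if vd is not None:
            Vd, Vp = self.encoder_.encode(vd, vp)

        cfg = ModelConfig(
            architecture=self.architecture,
            encoding=self.encoder_.embedding_kind,
            n_labels_drug=self.encoder_.drug_vocab_.n_labels,
            n_labels_protein=self.encoder_.protein_vocab_.n_labels,
            max_len_drug=self.max_len_drug,
            max_len_protein=self.max_len_protein,
            hidden_size=self.hidden_size, n_heads=self.n_heads,
            positional=self.positional, mask_pad=self.mask_pad,
            scale_mode=self.scale_mode, dropout=self.dropout)
        self.model_ = DTIModel(cfg, rng_init)
        opt = Adam(self.model_.parameters, lr=self.learning_rate)

        n = Xd.shape[0]
        best_score, best_state = -np.inf, None
        history = []
        for epoch in range(self.max_epochs):
            t0 = time.time()
            order = rng_shuffle.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                logits, _ = self.model_.forward(
                    Xd[idx], Xp[idx], train=True, dropout_rng=rng_drop)
                loss = bce_with_logits(logits, ty[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                      "seconds": round(time.time() - t0, 2)}
            if vd is not None:
                scores = self.model_.predict_proba(Vd, Vp, self.batch_size)
                if len(set(yv.tolist())) == 2:
                    val = float(evaluate_scores(yv, scores).PRAUC)
                    record["valid_prauc"] = val
                else:  # degenerate validation split: fall back to loss
                    val = -record["train_loss"]
            else:
                val = -record["train_loss"]
            if val > best_score:
                best_score = val
                best_state = self.model_.state_dict()
                record["best"] = True
            history.append(record)
            if self.verbose:
                print(f"epoch {epoch}: {record}", flush=True)
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.history_ = history
        return self

    # -- inference ------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        drugs, proteins = _unpack_X(X)
        Xd, Xp = self.encoder_.encode(drugs, proteins)
        return self.model_.predict_proba(Xd, Xp, self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold).astype(int)

    def evaluate(self, X, y, prauc_mode: str = "step") -> MetricSet:
        """All six metrics on a labeled set."""
        return evaluate_scores(np.asarray(y).astype(int),
                               self.decision_function(X),
                               threshold=self.threshold,
                               prauc_mode=prauc_mode)

    def attention_maps(self, X) -> list[ExpandedAttentionMap]:
        """Residue x atom attention maps (head-averaged, final layer)."""
        check_is_fitted(self, "model_")
        drugs, proteins = _unpack_X(X)
        Xd, Xp = self.encoder_.encode(drugs, proteins)
        maps = []
        for s in range(0, Xd.shape[0], self.batch_size):
            _, info = self.model_.forward(Xd[s:s + self.batch_size],
                                          Xp[s:s + self.batch_size])
            W = info["protein_weights"]  # (B, h, Lp, Ld)
            for b in range(W.shape[0]):
                i = s + b
                dsp, psp = self.encoder_.spans(drugs[i], proteins[i])
                maps.append(expand_attention(W[b], psp, dsp))
        return maps


    # -- persistence ----------------------------------------------------
    def save(self, directory) -> None:
        """Write model parameters, vocabularies and settings to a
        checkpoint directory."""
        check_is_fitted(self, "model_")
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.model_.save(d / "model.npz",
                         extra={"params": self.get_params(),
                                "history": self.history_})
        self.encoder_.drug_vocab_.save(d / "drug_vocab.txt")
        self.encoder_.protein_vocab_.save(d / "protein_vocab.txt")

    @classmethod
    def load(cls, directory) -> "DTIClassifier":
        from pathlib import Path

        d = Path(directory)
        model, extra = DTIModel.load(d / "model.npz")
        clf = cls(**extra["params"])
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = 2
        clf.history_ = extra["history"]
        clf.model_ = model
        clf.encoder_ = SequenceEncoder(
            clf.scheme, clf.max_len_drug, clf.max_len_protein,
            clf.min_freq, clf.max_vocab_drug, clf.max_vocab_protein)
        clf.encoder_.drug_vocab_ = tok.TokenVocabulary.load(
            d / "drug_vocab.txt")
        clf.encoder_.protein_vocab_ = tok.TokenVocabulary.load(
            d / "protein_vocab.txt")
        return clf


def multi_run(X, y, test_X, test_y, n_runs: int = 5, base_seed: int = 0,
              prauc_mode: str = "step", **estimator_params
              ) -> tuple[MetricSet, list[MetricSet]]:
    """Train and evaluate n_runs models re-seeded base_seed..+n_runs-1;
    report the arithmetic mean of each metric plus per-run values."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    per_run = []
    for r in range(n_runs):
        clf = DTIClassifier(random_state=base_seed + r, **estimator_params)
        clf.fit(X, y)
        per_run.append(clf.evaluate(test_X, test_y, prauc_mode=prauc_mode))
    return average_metrics(per_run), per_run
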