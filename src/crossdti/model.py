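"""The cross-attention DTI network: architectures, decoders, checkpoints.

A model is an embedding layer, a stack of one to three attention layers,
and a decoder head mapping the selected context matrix to a single
interaction probability. The architecture grid:

============  ===============  =====  ==============  ======
name          attention        depth  context         head
============  ===============  =====  ==============  ======
CA_DP         cross            1      drug+protein    CNN
CA2_DP        cross            2      drug+protein    CNN
CA3_DP        cross            3      drug+protein    CNN
CA_DP_FCL     cross            1      drug+protein    FCL
SA_DP         self             1      drug+protein    CNN
CA_D          cross            1      drug            CNN
CA_P          cross            1      protein         CNN
============  ===============  =====  ==============  ======

CA_P — protein context decoded by the CNN — is the default. The CNN head
is two blocks of (1D convolution along the sequence axis with features
as channels, ReLU, width-2 max pooling, dropout) followed by one linear
layer; the sigmoid that turns the resulting logit into a probability is
applied outside the head so the loss can work on logits. The FCL head is
two (linear, ReLU, dropout) blocks on the flattened context plus a final
linear layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import (Parameter, Tensor, add, concat, matmul, mul, relu,
                        reshape, maximum, _sigmoid_np)
from .attention import ProjectionParams, init_projection, multihead_context
from .encoding import HIDDEN_SIZE, MAX_LEN_DRUG, MAX_LEN_PROTEIN

#: name -> (mechanism, depth, context selection, head kind)
ARCHITECTURES = {
    "CA_DP": ("cross", 1, "drug+protein", "cnn"),
    "CA2_DP": ("cross", 2, "drug+protein", "cnn"),
    "CA3_DP": ("cross", 3, "drug+protein", "cnn"),
    "CA_DP_FCL": ("cross", 1, "drug+protein", "fcl"),
    "SA_DP": ("self", 1, "drug+protein", "cnn"),
    "CA_D": ("cross", 1, "drug", "cnn"),
    "CA_P": ("cross", 1, "protein", "cnn"),
}


@dataclass
class ModelConfig:
    """Architecture and size hyper-parameters of one model instance."""

    architecture: str = "CA_P"
    encoding: str = "learned"          # "learned" | "onehot"
    n_labels_drug: int = 64
    n_labels_protein: int = 32
    max_len_drug: int = MAX_LEN_DRUG
    max_len_protein: int = MAX_LEN_PROTEIN
    hidden_size: int = HIDDEN_SIZE
    n_heads: int = 4
    positional: bool | None = None     # None: on for learned, off for onehot
    pos_init_scale: float = 0.1        # SD of the positional table init
    mask_pad: bool = True
    scale_mode: str = "sqrt"           # softmax denominator: "sqrt" | "d"
    # CNN head (package-chosen defaults, configurable)
    conv_channels: tuple[int, int] = (64, 32)
    kernel_widths: tuple[int, int] = (3, 3)
    pool_width: int = 4
    dropout: float = 0.1
    # FCL head
    fcl_sizes: tuple[int, int] = (64, 32)

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {sorted(ARCHITECTURES)}")
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.positional is None:
            self.positional = self.encoding == "learned"

    @property
    def mechanism(self):
        return ARCHITECTURES[self.architecture][0]

    @property
    def depth(self):
        return ARCHITECTURES[self.architecture][1]

    @property
    def context_selection(self):
        return ARCHITECTURES[self.architecture][2]

    @property
    def head_kind(self):
        return ARCHITECTURES[self.architecture][3]

    @property
    def head_dim(self):
        return self.hidden_size // self.n_heads


def _conv1d(x: Tensor, W: Parameter, b: Parameter) -> Tensor:
    """Sequence-axis 1D convolution, features as channels.

    x: (B, T, Cin); W: (k, Cin, Cout); output (B, T-k+1, Cout).
    """
    k = W.shape[0]
    T = x.shape[1]
    out = None
    for j in range(k):
        term = matmul(x[:, j:T - k + 1 + j, :], W[j])
        out = term if out is None else add(out, term)
    return add(out, b)


def _maxpool(x: Tensor, width: int) -> Tensor:
    T = x.shape[1]
    n = T // width
    out = x[:, 0:n * width:width, :]
    for j in range(1, width):
        out = maximum(out, x[:, j:n * width:width, :])
    return out


def _dropout(x: Tensor, p: float, train: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not train or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return mul(x, keep)


class _CNNHead:
    """conv-ReLU-pool-dropout x2, then a single linear layer -> logit."""

    def __init__(self, cfg: ModelConfig, in_rows: int,
                 rng: np.random.Generator):
        c1, c2 = cfg.conv_channels
        k1, k2 = cfg.kernel_widths
        self.cfg = cfg

        def u(shape, fan_in):
            lim = 1.0 / np.sqrt(fan_in)
            return Parameter(rng.uniform(-lim, lim, size=shape))

        h = cfg.hidden_size
        self.W1 = u((k1, h, c1), k1 * h)
        self.b1 = Parameter(np.zeros(c1))
        self.W2 = u((k2, c1, c2), k2 * c1)
        self.b2 = Parameter(np.zeros(c2))
        t = (in_rows - k1 + 1) // cfg.pool_width
        t = (t - k2 + 1) // cfg.pool_width
        if t < 1:
            raise ValueError("context too short for the CNN head")
        self.flat = t * c2
        self.W3 = u((self.flat, 1), self.flat)
        self.b3 = Parameter(np.zeros(1))

    @property
    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def __call__(self, x: Tensor, train: bool, rng) -> Tensor:
        cfg = self.cfg
        x = _dropout(_maxpool(relu(_conv1d(x, self.W1, self.b1)),
                              cfg.pool_width), cfg.dropout, train, rng)
        x = _dropout(_maxpool(relu(_conv1d(x, self.W2, self.b2)),
                              cfg.pool_width), cfg.dropout, train, rng)
        x = reshape(x, (x.shape[0], self.flat))
        return reshape(add(matmul(x, self.W3), self.b3), (x.shape[0],))


class _FCLHead:
    """(linear, ReLU, dropout) x2 on the flattened context, then linear."""

    def __init__(self, cfg: ModelConfig, in_rows: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        n1, n2 = cfg.fcl_sizes
        self.flat = in_rows * cfg.hidden_size

        def u(shape, fan_in):
            lim = 1.0 / np.sqrt(fan_in)
            return Parameter(rng.uniform(-lim, lim, size=shape))

        self.W1, self.b1 = u((self.flat, n1), self.flat), Parameter(np.zeros(n1))
        self.W2, self.b2 = u((n1, n2), n1), Parameter(np.zeros(n2))
        self.W3, self.b3 = u((n2, 1), n2), Parameter(np.zeros(1))

    @property
    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def __call__(self, x: Tensor, train: bool, rng) -> Tensor:
        cfg = self.cfg
        x = reshape(x, (x.shape[0], self.flat))
        x = _dropout(relu(add(matmul(x, self.W1), self.b1)),
                     cfg.dropout, train, rng)
        x = _dropout(relu(add(matmul(x, self.W2), self.b2)),
                     cfg.dropout, train, rng)
        return reshape(add(matmul(x, self.W3), self.b3), (x.shape[0],))


def select_context(ctx_drug: Tensor | None, ctx_protein: Tensor | None,
                   selection: str) -> Tensor:
    """Pick the decoder input: [C^D; C^P] row-concatenated, or one alone."""
    if selection == "drug+protein":
        if ctx_drug is None or ctx_protein is None:
            raise ValueError("drug+protein selection requires both contexts")
        return concat([ctx_drug, ctx_protein], axis=1)
    if selection == "drug":
        if ctx_drug is None:
            raise ValueError("drug selection requires the drug context")
        return ctx_drug
    if selection == "protein":
        if ctx_protein is None:
            raise ValueError("protein selection requires the protein context")
        return ctx_protein
    raise ValueError(f"unknown context selection {selection!r}")


class DTIModel:
    """A full network instance with trainable parameters.

    Consumes integer label matrices (B, max_len) for drugs and proteins
    plus boolean masks of real positions, and produces logits; attention
    weights of the final layer are returned for interpretability.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        cfg = config
        h, d = cfg.n_heads, cfg.head_dim
        self._names: list[str] = []
        self._params: list[Parameter] = []

        if cfg.encoding == "learned":
            dim_d = dim_p = cfg.hidden_size
            self.tok_drug = Parameter(
                rng.standard_normal((cfg.n_labels_drug, cfg.hidden_size)))
            self.tok_protein = Parameter(
                rng.standard_normal((cfg.n_labels_protein, cfg.hidden_size)))
            self._register({"tok_drug": self.tok_drug,
                            "tok_protein": self.tok_protein})
        elif cfg.encoding == "onehot":
            dim_d, dim_p = cfg.n_labels_drug, cfg.n_labels_protein
            self.tok_drug = self.tok_protein = None
        else:
            raise ValueError(f"unknown encoding {cfg.encoding!r}")
        if cfg.positional:
            s = cfg.pos_init_scale
            self.pos_drug = Parameter(
                s * rng.standard_normal((cfg.max_len_drug, dim_d)))
            self.pos_protein = Parameter(
                s * rng.standard_normal((cfg.max_len_protein, dim_p)))
            self._register({"pos_drug": self.pos_drug,
                            "pos_protein": self.pos_protein})
        else:
            self.pos_drug = self.pos_protein = None

        self.layers: list[dict[str, ProjectionParams]] = []
        for k in range(cfg.depth):
            in_p = dim_p if k == 0 else cfg.hidden_size
            in_d = dim_d if k == 0 else cfg.hidden_size
            if cfg.mechanism == "cross":
                pp = init_projection(in_p, in_d, h, d, rng)
                pd = init_projection(in_d, in_p, h, d, rng)
            else:  # self-attention: each sequence attends itself
                pp = init_projection(in_p, in_p, h, d, rng)
                pd = init_projection(in_d, in_d, h, d, rng)
            self.layers.append({"p": pp, "d": pd})
            for side, pr in (("p", pp), ("d", pd)):
                self._register({f"layer{k}_{side}_{n}": w for n, w in
                                zip(("Wq", "Wk", "Wv", "W0"), pr.parameters)})

        rows = {"drug+protein": cfg.max_len_drug + cfg.max_len_protein,
                "drug": cfg.max_len_drug,
                "protein": cfg.max_len_protein}[cfg.context_selection]
        head_cls = _CNNHead if cfg.head_kind == "cnn" else _FCLHead
        self.head = head_cls(cfg, rows, rng)
        self._register({f"head_{i}": p for i, p in
                        enumerate(self.head.parameters)})

    def _register(self, named: dict[str, Parameter]) -> None:
        for n, p in named.items():
            self._names.append(n)
            self._params.append(p)

    @property
    def parameters(self) -> list[Parameter]:
        return self._params

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params))

    # -- forward --------------------------------------------------------
    def _embed(self, labels: np.ndarray, side: str) -> Tensor:
        from ._autodiff import embedding

        cfg = self.config
        if cfg.encoding == "learned":
            table = self.tok_drug if side == "drug" else self.tok_protein
            x = embedding(table, labels)
        else:
            width = (cfg.n_labels_drug if side == "drug"
                     else cfg.n_labels_protein)
            eye = np.eye(width, dtype=np.float32)
            onehot = eye[labels]
            onehot[labels == 0] = 0.0  # PAD rows are all-zero
            x = Tensor(onehot)
        pos = self.pos_drug if side == "drug" else self.pos_protein
        if pos is not None:
            x = add(x, embedding(pos, np.arange(labels.shape[1])))
        return x

    def forward(self, drug_labels: np.ndarray, prot_labels: np.ndarray,
                train: bool = False,
                dropout_rng: np.random.Generator | None = None
                ) -> tuple[Tensor, dict[str, np.ndarray]]:
        """Return (logits (B,), attention info of the final layer)."""
        cfg = self.config
        drug_mask = drug_labels != 0
        prot_mask = prot_labels != 0
        km_d = drug_mask if cfg.mask_pad else None
        km_p = prot_mask if cfg.mask_pad else None
        D = self._embed(drug_labels, "drug")
        P = self._embed(prot_labels, "protein")

        Wp = Wd = None
        for layer in self.layers:
            if cfg.mechanism == "cross":
                ctxP, Wp, _ = multihead_context(
                    P, D, layer["p"], km_d, km_p, cfg.scale_mode)
                ctxD, Wd, _ = multihead_context(
                    D, P, layer["d"], km_p, km_d, cfg.scale_mode)
            else:
                ctxP, Wp, _ = multihead_context(
                    P, P, layer["p"], km_p, km_p, cfg.scale_mode)
                ctxD, Wd, _ = multihead_context(
                    D, D, layer["d"], km_d, km_d, cfg.scale_mode)
            P, D = ctxP, ctxD

        ctx = select_context(D, P, cfg.context_selection)
        logits = self.head(ctx, train, dropout_rng)
        return logits, {"protein_weights": Wp, "drug_weights": Wd,
                        "drug_mask": drug_mask, "protein_mask": prot_mask}

    def predict_proba(self, drug_labels: np.ndarray,
                      prot_labels: np.ndarray,
                      batch_size: int = 128) -> np.ndarray:
        """Interaction probabilities, dropout inactive."""
        out = []
        for s in range(0, drug_labels.shape[0], batch_size):
            logits, _ = self.forward(drug_labels[s:s + batch_size],
                                     prot_labels[s:s + batch_size],
                                     train=False)
            out.append(_sigmoid_np(logits.data))
        return np.concatenate(out) if out else np.empty(0, dtype=np.float32)

    # -- checkpointing --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in zip(self._names, self._params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in zip(self._names, self._params):
            p.data = np.asarray(state[n], dtype=np.float32).copy()

    def save(self, path, extra: dict | None = None) -> None:
        meta = {"config": asdict(self.config), "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path) -> tuple["DTIModel", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            for key in ("conv_channels", "kernel_widths", "fcl_sizes"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict), np.random.default_rng(0))
            model.load_state_dict({k: data[k] for k in data.files
                                   if k != "__meta__"})
        return model, meta["extra"]
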