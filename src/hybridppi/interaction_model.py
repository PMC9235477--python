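"""Bottom-up sequence model: embedder, projection, contact map, probability.

The model follows the D-SCRIPT architecture family: per-residue
embeddings from a pluggable embedder are projected to a low dimension,
combined pairwise (absolute differences and elementwise products of the
two proteins' residue features), mixed by a 1x1 hidden layer, convolved
with a width-7 2D filter and squashed through a sigmoid into an n x m
inter-protein contact map. The interaction head max-pools the map
(width 9), sparsifies it against a learnable threshold (mean + gamma *
variance of the pooled entries) and maps the mean active intensity
through a steep logistic to the interaction probability.

Two embedders ship with the package:

* :class:`HashWindowEmbedder` — a deterministic stand-in whose residue
  vector is a pseudo-random function of the k-mer window centred on the
  residue (k = 5, 64 dims). It carries exact-match sequence signal and
  requires no external weights, which makes the whole pipeline testable
  offline.
* :class:`PrecomputedEmbedder` — an adapter over an HDF5 cache of
  per-protein (L x d0) matrices, the deployment route for features from
  a pretrained protein language model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    conv2d_same,
    conv2d_same_backward,
    kaiming_uniform,
    maxpool2d,
    maxpool2d_backward,
    sigmoid,
)
from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS + "X")

__all__ = [
    "EmbeddedSequence",
    "ModelConfig",
    "InteractionPrediction",
    "HashWindowEmbedder",
    "PrecomputedEmbedder",
    "InteractionModel",
    "embed_sequence",
    "predict",
    "contact_magnitude",
]


@dataclass
class EmbeddedSequence:
    """Per-residue embedding of one protein: an (L x d0) matrix."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValidationError("embedding must be a matrix with at least one row")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the reference settings: projection dimension 100,
    hidden dimension 50, convolution width 7, pooling width 9. Tiny
    configurations (e.g. d=20, h=10) are used for desk-scale training.
    """

    embedder_dim: int
    projection_dim: int = 100
    hidden_dim: int = 50
    conv_width: int = 7
    pool_width: int = 9
    dropout: float = 0.5
    embedder_tag: str = ""
    seed: int = 0
    dtype: str = "float32"  # compute precision; float64 for gradient checks

    def __post_init__(self):
        for name in ("embedder_dim", "projection_dim", "hidden_dim", "conv_width", "pool_width"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.conv_width % 2 != 1:
            raise ValidationError("convolution width must be odd")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must lie in [0, 1)")
        if self.dtype not in ("float32", "float64"):
            raise ValidationError("dtype must be 'float32' or 'float64'")


@dataclass
class InteractionPrediction:
    """Model output for one pair: probability and contact map.

    The contact map is emitted at full residue resolution (n x m for
    input lengths n and m); pooling happens only inside the probability
    head. Metadata records the 0-based residue-index convention.
    """

    probability: float
    contact_map: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.probability):
            raise ValidationError("probability must be finite")
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError("probability must lie in [0, 1]")


def _validate_sequence(seq: str) -> str:
    if not seq:
        raise ValidationError("sequence must have length >= 1")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise ValidationError(f"illegal residue {ch!r} at position {i}")
    return seq


class HashWindowEmbedder:
    """Deterministic stand-in embedder with window-local features.

    The vector for residue i is a pseudo-random standard-normal draw
    seeded by the k-mer window centred on i (sequence ends padded with
    '-'), so identical windows in any two sequences map to identical
    rows. Deterministic across processes: the seed is derived from a
    cryptographic digest, never from Python's salted hash().
    """

    def __init__(self, dim: int = 64, k: int = 5, seed: int = 0):
        if k % 2 != 1:
            raise ValidationError("window size k must be odd")
        self.dim = dim
        self.k = k
        self.seed = seed
        self.tag = f"hash-window-k{k}-d{dim}-s{seed}"
        self._cache: dict[str, np.ndarray] = {}

    def _window_vector(self, window: str) -> np.ndarray:
        vec = self._cache.get(window)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}|{window}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            self._cache[window] = vec
        return vec

    def __call__(self, seq: str) -> np.ndarray:
        seq = _validate_sequence(seq)
        half = self.k // 2
        padded = "-" * half + seq + "-" * half
        return np.stack(
            [self._window_vector(padded[i:i + self.k]) for i in range(len(seq))]
        )


class PrecomputedEmbedder:
    """Adapter over a mapping / HDF5 cache of per-protein embeddings.

    Deployment route for pretrained protein-language-model features
    (e.g. concatenated hidden-layer activations); lookup is by protein
    id rather than by sequence.
    """

    def __init__(self, store, dim: int, tag: str = "precomputed"):
        self._store = store
        self.dim = dim
        self.tag = tag

    def get(self, protein_id: str) -> np.ndarray:
        if protein_id not in self._store:
            raise KeyError(f"no embedding cached for protein {protein_id!r}")
        mat = np.asarray(self._store[protein_id], dtype=float)
        if mat.ndim != 2 or mat.shape[1] != self.dim:
            raise ValidationError(
                f"cached embedding for {protein_id!r} has shape {mat.shape}, expected (*, {self.dim})"
            )
        return mat


def embed_sequence(seq: str, embedder, protein_id: str = "") -> EmbeddedSequence:
    """Embed an amino-acid sequence into an (L x d0) matrix."""
    matrix = embedder(seq)
    return EmbeddedSequence(protein_id=protein_id, matrix=matrix)


class InteractionModel:
    """The trainable network; parameters live in a flat dict of arrays.

    forward() returns the prediction plus a cache of intermediates;
    backward() consumes the cache and upstream gradients and returns
    parameter gradients. Both are deterministic given the seed.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        d0, d, h, k = (
            config.embedder_dim,
            config.projection_dim,
            config.hidden_dim,
            config.conv_width,
        )
        rng = np.random.default_rng(config.seed)
        self.dtype = np.dtype(config.dtype)
        self.params = {
            "Wp": kaiming_uniform(rng, (d0, d), d0),
            "bp": kaiming_uniform(rng, (d,), d0),
            "Wh": kaiming_uniform(rng, (2 * d, h), 2 * d),
            "bh": kaiming_uniform(rng, (h,), 2 * d),
            "Wc": kaiming_uniform(rng, (h, k, k), h * k * k),
            "bc": np.zeros(()),
            "gamma": np.zeros(()),
            "kslope": np.full((), 20.0),
        }
        self.params = {k_: v.astype(self.dtype) for k_, v in self.params.items()}

    # ------------------------------------------------------------------
    def forward(self, E1: np.ndarray, E2: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None):
        cfg = self.config
        p = self.params
        for E in (E1, E2):
            if E.shape[1] != cfg.embedder_dim:
                raise ValidationError(
                    f"embedding dim {E.shape[1]} does not match model embedder_dim {cfg.embedder_dim}"
                )
        E1 = E1.astype(self.dtype, copy=False)
        E2 = E2.astype(self.dtype, copy=False)
        cache: dict = {"E1": E1, "E2": E2}

        Zp1 = E1 @ p["Wp"] + p["bp"]
        Zp2 = E2 @ p["Wp"] + p["bp"]
        Z1 = np.maximum(Zp1, 0.0)
        Z2 = np.maximum(Zp2, 0.0)
        if train and cfg.dropout > 0:
            if dropout_rng is None:
                dropout_rng = np.random.default_rng(cfg.seed)
            keep = 1.0 - cfg.dropout
            m1 = (dropout_rng.random(Z1.shape) < keep).astype(self.dtype) / keep
            m2 = (dropout_rng.random(Z2.shape) < keep).astype(self.dtype) / keep
            Z1 = Z1 * m1
            Z2 = Z2 * m2
            cache["m1"], cache["m2"] = m1, m2
        cache["Zp1"], cache["Zp2"], cache["Z1"], cache["Z2"] = Zp1, Zp2, Z1, Z2

        diff = Z1[:, None, :] - Z2[None, :, :]
        Dabs = np.abs(diff)
        Prod = Z1[:, None, :] * Z2[None, :, :]
        cache["sign"] = np.sign(diff)
        cache["Dabs"], cache["Prod"] = Dabs, Prod

        d = cfg.projection_dim
        Hpre = Dabs @ p["Wh"][:d] + Prod @ p["Wh"][d:] + p["bh"]
        H = np.maximum(Hpre, 0.0)
        cache["Hpre"] = Hpre

        G, convctx = conv2d_same(H, p["Wc"], float(p["bc"]))
        C = sigmoid(G)
        cache["convctx"], cache["C"] = convctx, C

        Q, arg = maxpool2d(C, cfg.pool_width)
        mu = float(Q.mean())
        var = float(Q.var())
        gamma_eff = max(float(p["gamma"]), 0.0)
        tau = mu + gamma_eff * var
        A = Q - tau
        active = A > 0
        count = int(active.sum())
        s = float(A[active].sum()) / (count + 1)
        k_eff = max(float(p["kslope"]), 0.0)
        yhat = float(sigmoid(k_eff * (s - 0.5)))
        cache.update(Q=Q, arg=arg, mu=mu, var=var, tau=tau, active=active,
                     count=count, s=s, yhat=yhat, gamma_eff=gamma_eff, k_eff=k_eff)
        return yhat, C, cache

    # ------------------------------------------------------------------
    def backward(self, cache: dict, d_yhat: float, dC_scalar: float = 0.0) -> dict:
        """Parameter gradients for d(loss)/d(yhat) plus a uniform
        contact-map gradient ``dC_scalar`` (per-entry, e.g. from the
        magnitude regulariser)."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        yhat, s, k_eff = cache["yhat"], cache["s"], cache["k_eff"]
        Q, active, count = cache["Q"], cache["active"], cache["count"]
        # logistic head
        dz = d_yhat * yhat * (1.0 - yhat)
        if float(p["kslope"]) >= 0.0:
            grads["kslope"] = np.asarray(dz * (s - 0.5))
        ds = dz * k_eff
        dA_active = ds / (count + 1)
        dQ = np.zeros_like(Q)
        dQ[active] += dA_active
        dtau = -dA_active * count
        if float(p["gamma"]) >= 0.0:
            grads["gamma"] = np.asarray(dtau * cache["var"])
        # tau = mu + gamma*var, both functions of Q
        nQ = Q.size
        dQ += dtau / nQ
        dvar = dtau * cache["gamma_eff"]
        dQ += dvar * 2.0 * (Q - cache["mu"]) / nQ

        C = cache["C"]
        dC = maxpool2d_backward(dQ, cache["arg"], C.shape)
        if dC_scalar != 0.0:
            dC += dC_scalar
        dG = dC * C * (1.0 - C)

        dWc, dbc, dH = conv2d_same_backward(dG, cache["convctx"], p["Wc"])
        grads["Wc"] = dWc
        grads["bc"] = np.asarray(dbc)

        d = self.config.projection_dim
        dHpre = dH * (cache["Hpre"] > 0)
        grads["Wh"] = np.concatenate([
            np.tensordot(cache["Dabs"], dHpre, axes=([0, 1], [0, 1])),
            np.tensordot(cache["Prod"], dHpre, axes=([0, 1], [0, 1])),
        ])
        grads["bh"] = dHpre.sum(axis=(0, 1))
        dDabs = dHpre @ p["Wh"][:d].T
        dProd = dHpre @ p["Wh"][d:].T
        sg = cache["sign"]
        Z1, Z2 = cache["Z1"], cache["Z2"]
        dZ1 = np.einsum("ijd,ijd->id", dDabs, sg) + np.einsum("ijd,jd->id", dProd, Z2)
        dZ2 = -np.einsum("ijd,ijd->jd", dDabs, sg) + np.einsum("ijd,id->jd", dProd, Z1)
        if "m1" in cache:
            dZ1 = dZ1 * cache["m1"]
            dZ2 = dZ2 * cache["m2"]
        dZp1 = dZ1 * (cache["Zp1"] > 0)
        dZp2 = dZ2 * (cache["Zp2"] > 0)
        grads["Wp"] = cache["E1"].T @ dZp1 + cache["E2"].T @ dZp2
        grads["bp"] = dZp1.sum(axis=0) + dZp2.sum(axis=0)
        return grads

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps(self.config.__dict__)
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "InteractionModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            model = cls(ModelConfig(**meta))
            for k in model.params:
                model.params[k] = np.asarray(data[k])
        return model


def predict(e1: EmbeddedSequence, e2: EmbeddedSequence,
            model: InteractionModel, config: ModelConfig | None = None) -> InteractionPrediction:
    """Predict interaction probability and contact map for a pair."""
    if config is not None and config != model.config:
        raise ValidationError("config does not match the model's configuration")
    yhat, C, _ = model.forward(e1.matrix, e2.matrix, train=False)
    return InteractionPrediction(
        probability=yhat,
        contact_map=C,
        metadata={
            "id_a": e1.protein_id,
            "id_b": e2.protein_id,
            "shape": C.shape,
            "resolution": "per-residue",
            "index_base": 0,
            "embedder_tag": model.config.embedder_tag,
        },
    )


def contact_magnitude(pred: InteractionPrediction) -> float:
    """Mean of the contact-map entries; zero iff the map is all zero."""
    return float(np.mean(pred.contact_map))
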