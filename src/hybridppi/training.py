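"""Training-set assembly, the co-supervised loss, and the training loop.

The loss mixes three terms,

    L = lambda * (L_BCE + g_p * L_GLIDE) + (1 - lambda) * L_MAG,

where L_BCE is binary cross-entropy against the interaction label,
L_GLIDE is binary cross-entropy against the network-derived target
1[GLIDE(p,q) >= threshold(g_t)] (link-plausibility co-supervision), and
L_MAG is the mean contact-map magnitude, which pushes the model towards
sparse, realistic contact maps. At g_p = 0 the loss reduces exactly to
the plain sequence-model (D-SCRIPT-form) objective.

GLIDE targets are computed on the network defined by the positive
training examples alone. Training positives are edges of that network,
so their target is 1 by construction; negatives are scored and binarized
at the g_t percentile of the negatives' score distribution (a config
switch allows thresholding over all scored pairs instead). Pairs with an
endpoint outside the network cannot be scored by graph measures: they are
excluded from the L_GLIDE term and tallied, rather than given a target
of 0 on absent evidence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .network_scoring import (
    GlideParams,
    GlideScoreTable,
    build_network,
    glide_table,
    percentile_threshold,
)

BCE_EPS = 1e-7

__all__ = [
    "ExamplePair",
    "LossConfig",
    "TrainConfig",
    "TrainingData",
    "GlideTargetResult",
    "TrainResult",
    "sample_negatives",
    "sample_negatives_low_glide",
    "make_glide_targets",
    "loss_bce",
    "loss_glide",
    "total_loss",
    "dscript_loss",
    "train",
]


@dataclass
class ExamplePair:
    """One labelled training/evaluation pair.

    ``glide_target`` is None until targets are attached; it stays None
    (and ``flagged`` becomes True) for pairs that cannot be scored on
    the positive-example network. ``label`` may be None only for
    unlabelled query pairs; training requires 0/1 labels.
    """

    id_a: str
    id_b: str
    label: int | None
    glide_target: int | None = None
    glide_score: float | None = None
    flagged: bool = False

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValidationError(f"self-pair rejected: ({self.id_a}, {self.id_b})")
        if self.label not in (0, 1, None):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


@dataclass(frozen=True)
class LossConfig:
    """Loss mixing weights: lambda, g_p and the g_t percentile."""

    lam: float = 0.05
    g_p: float = 0.2
    g_t: float = 92.5
    threshold_population: str = "negatives"  # or "all"

    def __post_init__(self):
        if not (0 <= self.lam <= 1):
            raise ValidationError(f"lambda must lie in [0, 1], got {self.lam}")
        if not (0 <= self.g_p <= 1):
            raise ValidationError(f"g_p must lie in [0, 1], got {self.g_p}")
        if not (0 < self.g_t < 100):
            raise ValidationError(f"g_t must lie in (0, 100), got {self.g_t}")
        if self.threshold_population not in ("negatives", "all"):
            raise ValidationError("threshold_population must be 'negatives' or 'all'")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (reference defaults: Adam, lr 1e-3,
    batch 25, 10 epochs, 10:1 negative sampling)."""

    batch_size: int = 25
    learning_rate: float = 0.001
    optimizer: str = "adam"
    epochs: int = 10
    negative_ratio: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be positive")
        if self.negative_ratio < 1:
            raise ValidationError("negative_ratio must be >= 1")
        if not (self.learning_rate > 0):
            raise ValidationError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer: {self.optimizer!r}")


# ---------------------------------------------------------------------------
# negative sampling

def _pair_key(a, b) -> frozenset:
    return frozenset((a, b))


def sample_negatives(proteins: Iterable[str], positives: Iterable, ratio: int,
                     seed: int) -> list[tuple[str, str]]:
    """Sample ``ratio * |positives|`` distinct non-positive pairs.

    Reproducible under the seed; raises with the feasible maximum when
    the candidate pool is too small.
    """
    prots = sorted(set(proteins))
    pos_keys = {_pair_key(a, b) for a, b in positives}
    n = len(prots)
    possible = n * (n - 1) // 2 - len(pos_keys)
    needed = ratio * len(pos_keys)
    if needed > possible:
        raise ValidationError(
            f"cannot sample {needed} negatives: only {possible} non-positive pairs exist"
        )
    rng = np.random.default_rng(seed)
    if needed > possible // 2:
        pool = [
            (a, b)
            for a, b in itertools.combinations(prots, 2)
            if _pair_key(a, b) not in pos_keys
        ]
        idx = rng.choice(len(pool), size=needed, replace=False)
        return [pool[i] for i in sorted(idx)]
    out: list[tuple[str, str]] = []
    chosen: set[frozenset] = set()
    while len(out) < needed:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = prots[min(i, j)], prots[max(i, j)]
        key = _pair_key(a, b)
        if key in pos_keys or key in chosen:
            continue
        chosen.add(key)
        out.append((a, b))
    return out


def sample_negatives_low_glide(candidates: Sequence[tuple], table: GlideScoreTable,
                               cutoff_percentile: float, n: int, seed: int) -> list[tuple]:
    """Pick ``n`` candidate pairs whose GLIDE score falls below a
    percentile cutoff of the candidates' score distribution.

    Only in-network (scoreable) candidates are eligible, since graph
    measures are undefined for off-network proteins. A cutoff of 100
    degenerates to a plain random sample over in-network candidates.
    """
    if not (0 < cutoff_percentile <= 100):
        raise ValidationError(f"cutoff percentile must lie in (0, 100], got {cutoff_percentile}")
    lookup = {frozenset(pq): s for pq, s in zip(table.pairs, table.scores)}
    scored = []
    for pair in candidates:
        key = frozenset(pair)
        if key not in lookup:
            raise ValidationError(f"candidate pair {tuple(pair)} not scored in table")
        if key in table.flagged:
            continue
        scored.append((pair, lookup[key]))
    if cutoff_percentile == 100:
        eligible = [p for p, _ in scored]
    else:
        values = np.array([s for _, s in scored])
        cutoff = float(np.percentile(values, cutoff_percentile, method="linear"))
        eligible = [p for p, s in scored if s < cutoff]
    if len(eligible) < n:
        raise ValidationError(
            f"only {len(eligible)} eligible low-score candidates, need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# GLIDE supervision targets

@dataclass
class GlideTargetResult:
    """Examples with attached targets plus the scoring provenance."""

    examples: list
    table: GlideScoreTable
    threshold: float
    n_skipped: int

    def __iter__(self):
        return iter(self.examples)

    def __len__(self):
        return len(self.examples)


def make_glide_targets(train_positives: Iterable, examples: Sequence[ExamplePair],
                       params: GlideParams | None = None, g_t: float = 92.5,
                       threshold_population: str = "negatives") -> GlideTargetResult:
    """Attach binarized link-plausibility targets to training examples.

    The scoring network is built from the positive training pairs alone.
    Positives are that network's own edges, so their target is 1 without
    scoring; negatives are scored and binarized at the ``g_t`` percentile.
    """
    params = params or GlideParams()
    positives = list(train_positives)
    if not positives:
        raise ValidationError("empty positive set: no network to score on")
    net = build_network([(a, b, 1.0) for a, b in positives])

    negatives = [ex for ex in examples if ex.label == 0]
    neg_pairs = [(ex.id_a, ex.id_b) for ex in negatives]
    table = glide_table(net, neg_pairs, params)
    lookup = dict(zip((frozenset(pq) for pq in table.pairs), table.scores))

    if threshold_population == "negatives":
        population = [
            float(s) for pq, s in zip(table.pairs, table.scores)
            if frozenset(pq) not in table.flagged
        ]
    elif threshold_population == "all":
        pos_table = glide_table(net, positives, params)
        population = [
            float(s) for pq, s in zip(table.pairs, table.scores)
            if frozenset(pq) not in table.flagged
        ] + [float(s) for s in pos_table.scores]
    else:
        raise ValidationError("threshold_population must be 'negatives' or 'all'")
    if not population:
        raise ValidationError("no scoreable pairs to take a percentile over")
    threshold = float(np.percentile(np.array(population), g_t, method="linear"))

    out = []
    n_skipped = 0
    for ex in examples:
        if ex.label == 1:
            out.append(replace(ex, glide_target=1, glide_score=None, flagged=False))
            continue
        key = ex.key
        if key in table.flagged:
            out.append(replace(ex, glide_target=None, glide_score=None, flagged=True))
            n_skipped += 1
        else:
            s = float(lookup[key])
            out.append(replace(ex, glide_target=int(s >= threshold),
                               glide_score=s, flagged=False))
    return GlideTargetResult(examples=out, table=table, threshold=threshold,
                             n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# loss terms

def loss_bce(y_hat: float, label: int, eps: float = BCE_EPS) -> float:
    """Binary cross-entropy with clamping of the prediction to
    (eps, 1 - eps)."""
    if label not in (0, 1):
        raise ValidationError(f"label must be 0 or 1, got {label!r}")
    y = min(max(float(y_hat), eps), 1.0 - eps)
    return -(label * math.log(y) + (1 - label) * math.log(1.0 - y))


def loss_glide(y_hat: float, glide_target: int | None) -> float:
    """BCE against the binarized link-plausibility target; pairs without
    a target contribute 0 (the caller tallies them)."""
    if glide_target is None:
        return 0.0
    return loss_bce(y_hat, glide_target)


def dscript_loss(y_hat: float, label: int, contact_mag: float, lam: float = 0.05) -> float:
    """The plain sequence-model objective: lam*BCE + (1-lam)*magnitude."""
    return lam * loss_bce(y_hat, label) + (1.0 - lam) * contact_mag


def total_loss(y_hat: float, label: int, glide_target: int | None,
               contact_mag: float, cfg: LossConfig) -> float:
    """The full co-supervised objective; reduces bit-exactly to
    :func:`dscript_loss` at g_p = 0."""
    lb = loss_bce(y_hat, label)
    lg = loss_glide(y_hat, glide_target)
    return cfg.lam * (lb + cfg.g_p * lg) + (1.0 - cfg.lam) * contact_mag


def _d_loss_d_yhat(y_hat: float, label: int, glide_target: int | None,
                   cfg: LossConfig) -> float:
    """d(total_loss)/d(y_hat), with the same clamping as the loss."""
    y = min(max(float(y_hat), BCE_EPS), 1.0 - BCE_EPS)
    d = (y - label) / (y * (1.0 - y))
    if glide_target is not None and cfg.g_p > 0:
        d += cfg.g_p * (y - glide_target) / (y * (1.0 - y))
    return cfg.lam * d


# ---------------------------------------------------------------------------
# training loop

@dataclass
class TrainingData:
    """Pairs plus an id -> (L x d0) embedding matrix lookup."""

    pairs: list
    embeddings: dict
    val_pairs: list = field(default_factory=list)

    def __post_init__(self):
        for ex in list(self.pairs) + list(self.val_pairs):
            for pid in (ex.id_a, ex.id_b):
                if pid not in self.embeddings:
                    raise ValidationError(f"missing embedding for protein {pid!r}")

    @property
    def class_ratio(self) -> tuple[int, int]:
        pos = sum(ex.label for ex in self.pairs)
        return pos, len(self.pairs) - pos


@dataclass
class TrainResult:
    model: object
    history: list
    best_epoch: int
    best_val_aupr: float | None


def train(model, dataset: TrainingData, loss_cfg: LossConfig,
          train_cfg: TrainConfig) -> TrainResult:
    """End-to-end training from seeded initialisation.

    Records per-epoch mean training loss and (when a validation split is
    provided) validation AUPR; the best epoch is tracked by validation
    AUPR. Deterministic for a fixed seed in a single-threaded run.
    """
    from ._nn import Adam
    from .evaluation import aupr

    rng = np.random.default_rng(train_cfg.seed)
    dropout_rng = np.random.default_rng(train_cfg.seed + 2**20)
    opt = Adam(model.params, lr=train_cfg.learning_rate)
    pairs = list(dataset.pairs)
    n = len(pairs)
    skipped = sum(1 for ex in pairs if ex.label == 0 and ex.glide_target is None)

    history = []
    best_epoch, best_val = -1, None
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            batch = [pairs[i] for i in order[start:start + train_cfg.batch_size]]
            grads_sum = None
            for ex in batch:
                E1 = dataset.embeddings[ex.id_a]
                E2 = dataset.embeddings[ex.id_b]
                yhat, C, cache = model.forward(E1, E2, train=True, dropout_rng=dropout_rng)
                mag = float(np.mean(C))
                losses.append(total_loss(yhat, ex.label, ex.glide_target, mag, loss_cfg))
                d_yhat = _d_loss_d_yhat(yhat, ex.label, ex.glide_target, loss_cfg)
                dC_scalar = (1.0 - loss_cfg.lam) / C.size
                g = model.backward(cache, d_yhat, dC_scalar)
                if grads_sum is None:
                    grads_sum = g
                else:
                    for k in grads_sum:
                        grads_sum[k] += g[k]
            for k in grads_sum:
                grads_sum[k] = grads_sum[k] / len(batch)
            opt.step(grads_sum)
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "skipped_glide_pairs": skipped}
        if dataset.val_pairs:
            labels, scores = [], []
            for ex in dataset.val_pairs:
                yhat, _, _ = model.forward(dataset.embeddings[ex.id_a],
                                           dataset.embeddings[ex.id_b], train=False)
                labels.append(ex.label)
                scores.append(yhat)
            record["val_aupr"] = aupr(labels, scores)
            if best_val is None or record["val_aupr"] > best_val:
                best_val, best_epoch = record["val_aupr"], epoch
        history.append(record)
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_aupr=best_val)
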