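"""Evaluation protocols for link prediction under class imbalance.

Covers threshold-free metrics (AUPR by step-wise summation, AUROC, FPR
at fixed recall), degree- and distance-stratified breakdowns, hub-edge
filtering, and the spanning-tree-protected sparsification benchmark in
which a fraction 1-p of edges is held out as the positive test set while
a random spanning tree keeps the training subnetwork connected.

AUPR is the preferred headline metric here: with negatives sampled at
10:1 a random ranking scores ~0.091 AUPR but still 0.5 AUROC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .errors import ValidationError
from .network_scoring import PPINetwork

DEFAULT_HUB_CUTOFF = 21
DEFAULT_DEGREE_BIN_EDGES = (2, 6, 11, 21)

__all__ = [
    "EvaluationReport",
    "SparsifiedSplit",
    "aupr",
    "auroc",
    "fpr_at_recall",
    "stratify_by_max_degree",
    "stratify_by_distance",
    "filter_hub_edges",
    "sparsify",
    "evaluate",
]


def _check_inputs(labels, scores):
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValidationError("labels and scores must be aligned 1-D sequences")
    if labels.size == 0:
        raise ValidationError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    return labels, scores


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve by step-wise (non-
    interpolated) summation; tied scores enter threshold groups
    together."""
    labels, scores = _check_inputs(labels, scores)
    return float(average_precision_score(labels, scores))


def auroc(labels, scores) -> float:
    """Area under the ROC curve (equals the Mann-Whitney concordance
    probability, ties counted half)."""
    labels, scores = _check_inputs(labels, scores)
    return float(roc_auc_score(labels, scores))


def fpr_at_recall(labels, scores, recall_level: float) -> float:
    """False-positive rate at the most permissive threshold achieving at
    least the requested recall; tied scores form one threshold group."""
    if not (0 < recall_level <= 1):
        raise ValidationError(f"recall level must lie in (0, 1], got {recall_level}")
    labels, scores = _check_inputs(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    idx = np.searchsorted(tpr, recall_level - 1e-12, side="left")
    if idx >= len(tpr):
        raise ValidationError(f"recall {recall_level} unreachable")
    return float(fpr[idx])


# ---------------------------------------------------------------------------
# stratification

def _require_in_network(pairs, net: PPINetwork):
    for a, b in pairs:
        if not (net.has_node(a) and net.has_node(b)):
            missing = a if not net.has_node(a) else b
            raise ValidationError(f"protein {missing!r} not in the network")


def stratify_by_max_degree(pairs, net: PPINetwork, bin_edges=DEFAULT_DEGREE_BIN_EDGES) -> dict:
    """Partition pairs by M = max of the endpoint degrees.

    Default strata are 2-5, 6-10, 11-20 and >=21 (hub-involving pairs),
    with an underflow stratum for M below the first edge.
    """
    edges = tuple(bin_edges)
    if len(edges) < 1 or any(edges[i] >= edges[i + 1] for i in range(len(edges) - 1)):
        raise ValidationError("bin edges must be strictly increasing")
    _require_in_network(pairs, net)
    labels = [f"<{edges[0]}"]
    for i in range(len(edges) - 1):
        labels.append(f"{edges[i]}-{edges[i + 1] - 1}")
    labels.append(f">={edges[-1]}")
    out = {lab: [] for lab in labels}
    for a, b in pairs:
        m = max(net.degree(a), net.degree(b))
        pos = np.searchsorted(edges, m, side="right")
        out[labels[pos]].append((a, b))
    return out


def stratify_by_distance(pairs, net: PPINetwork) -> dict:
    """Partition pairs by unweighted shortest-path distance; pairs in
    different components go to the 'inf' stratum."""
    _require_in_network(pairs, net)
    out: dict = {}
    cache: dict = {}
    for a, b in pairs:
        if a not in cache:
            cache[a] = nx.single_source_shortest_path_length(net.graph, a)
        d = cache[a].get(b)
        key = "inf" if d is None else d
        out.setdefault(key, []).append((a, b))
    return out


def filter_hub_edges(pairs, net: PPINetwork, cutoff: int = DEFAULT_HUB_CUTOFF) -> list:
    """Drop pairs where either endpoint is a hub (degree >= cutoff)."""
    _require_in_network(pairs, net)
    return [
        (a, b) for a, b in pairs
        if net.degree(a) < cutoff and net.degree(b) < cutoff
    ]


# ---------------------------------------------------------------------------
# sparsification benchmark

@dataclass
class SparsifiedSplit:
    """A sparsified training network plus its held-out positive edges."""

    p: float
    network: PPINetwork
    held_out_positives: list
    seed: int
    metadata: dict = field(default_factory=dict)


def sparsify(net: PPINetwork, p: float, seed: int) -> SparsifiedSplit:
    """Keep round(p * |E|) edges while protecting a random spanning tree.

    The spanning tree (grown from a seeded random edge order) guarantees
    the kept subnetwork stays connected on the full node set; the
    remaining kept edges are drawn uniformly from the non-tree edges.
    Held-out positives are exactly E \\ E_p. Rounding is half-up, with
    tree edges counted inside the kept budget.
    """
    if not net.is_connected():
        raise ValidationError("sparsify requires a connected network")
    if not (0 < p <= 1):
        raise ValidationError(f"p must lie in (0, 1], got {p}")
    n_edges = net.n_edges
    n_nodes = net.n_nodes
    target = math.floor(p * n_edges + 0.5)
    if target < n_nodes - 1:
        p_min = (n_nodes - 1) / n_edges
        raise ValidationError(
            f"p={p} keeps {target} edges but a spanning tree needs {n_nodes - 1}; "
            f"smallest feasible p is about {p_min:.4f}"
        )
    rng = np.random.default_rng(seed)
    edges = sorted((min(a, b), max(a, b), w) for a, b, w in net.edges())
    order = rng.permutation(len(edges))

    parent = {v: v for v in net.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_idx, rest_idx = [], []
    for i in order:
        a, b, _ = edges[i]
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree_idx.append(i)
        else:
            rest_idx.append(i)
    extra = target - len(tree_idx)
    kept = set(tree_idx)
    if extra > 0 and rest_idx:
        pick = rng.choice(len(rest_idx), size=min(extra, len(rest_idx)), replace=False)
        kept.update(rest_idx[i] for i in pick)

    sub = PPINetwork()
    for v in net.nodes:
        sub.add_node(v)
    held_out = []
    for i, (a, b, w) in enumerate(edges):
        if i in kept:
            sub.add_edge(a, b, w)
        else:
            held_out.append((a, b))
    return SparsifiedSplit(
        p=p, network=sub, held_out_positives=held_out, seed=seed,
        metadata={
            "n_nodes": n_nodes, "n_edges_full": n_edges,
            "n_edges_kept": sub.n_edges, "n_held_out": len(held_out),
            "tree": "seeded random-edge-order spanning tree",
        },
    )


# ---------------------------------------------------------------------------
# assembled report

@dataclass
class EvaluationReport:
    """All metrics for one evaluation set, optionally stratified."""

    aupr: float
    auroc: float
    fpr_at: dict
    n_pos: int
    n_neg: int
    strata: dict | None = None

    def to_dict(self) -> dict:
        out = {"aupr": self.aupr, "auroc": self.auroc,
               "n_pos": self.n_pos, "n_neg": self.n_neg}
        for level, v in self.fpr_at.items():
            out[f"fpr_at_{level}"] = v
        if self.strata is not None:
            out["strata"] = {
                str(k): (v.to_dict() if isinstance(v, EvaluationReport) else v)
                for k, v in self.strata.items()
            }
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_flat_rows(self, stratum: str = "overall") -> list:
        rows = [{"stratum": stratum, **{k: v for k, v in self.to_dict().items()
                                        if k != "strata"}}]
        if self.strata:
            for key, rep in self.strata.items():
                if isinstance(rep, EvaluationReport):
                    rows.extend(rep.to_flat_rows(str(key)))
                else:
                    rows.append({"stratum": str(key), **rep})
        return rows


def evaluate(labels, scores, recall_levels=(0.1, 0.5), pairs=None,
             net: PPINetwork | None = None, strata: str | None = None) -> EvaluationReport:
    """Assemble AUPR, AUROC and FPR@recall, optionally broken down by
    max-degree or shortest-path-distance strata of the pairs."""
    labels, scores = _check_inputs(labels, scores)
    fprs = {lvl: fpr_at_recall(labels, scores, lvl) for lvl in recall_levels}
    report = EvaluationReport(
        aupr=aupr(labels, scores), auroc=auroc(labels, scores), fpr_at=fprs,
        n_pos=int(labels.sum()), n_neg=int((1 - labels).sum()),
    )
    if strata is not None:
        if pairs is None or net is None:
            raise ValidationError("stratified evaluation needs pairs and a network")
        if strata == "degree":
            groups = stratify_by_max_degree(pairs, net)
        elif strata == "distance":
            groups = stratify_by_distance(pairs, net)
        else:
            raise ValidationError(f"unknown stratification: {strata!r}")
        index = {frozenset(pq): i for i, pq in enumerate(pairs)}
        report.strata = {}
        for key, group in groups.items():
            if not group:
                continue
            idx = [index[frozenset(pq)] for pq in group]
            sub_l, sub_s = labels[idx], scores[idx]
            if len(np.unique(sub_l)) < 2:
                report.strata[key] = {
                    "n_pos": int(sub_l.sum()), "n_neg": int((1 - sub_l).sum()),
                    "note": "single-class stratum; threshold-free metrics undefined",
                }
            else:
                report.strata[key] = evaluate(sub_l, sub_s, recall_levels)
    return report
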