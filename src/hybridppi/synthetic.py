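"""Synthetic PPI benchmarks: networks, sequences and labelled splits.

The generators emulate the features of experimental PPI data that the
rest of the package depends on, without any download:

* degree-heterogeneous, community-structured interaction networks with
  hubs (a degree-corrected block-model construction with a connectivity
  repair pass);
* protein sequences that carry learnable interaction signal — every
  community has a motif planted into its members' sequences, so
  interacting (mostly intra-community) pairs share detectable k-mers;
* labelled example sets at a configurable negative:positive ratio
  (default 10:1, the conventional PPI class imbalance);
* an optional label-noise mechanism that plants "truly interacting"
  pairs into the negative set, chosen preferentially among same-community
  pairs with many common neighbours — exactly the pairs whose
  link-plausibility (GLIDE) scores are high, which is the situation
  network co-supervision is meant to mitigate.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .interaction_model import AMINO_ACIDS
from .network_scoring import PPINetwork
from .training import ExamplePair, sample_negatives

__all__ = [
    "BenchmarkConfig",
    "SyntheticBenchmark",
    "synth_network",
    "synth_benchmark",
    "motif_cooccurrence_scores",
    "write_benchmark",
]


def synth_network(n_nodes: int, hub_fraction: float = 0.05,
                  community_count: int = 4, seed: int = 0,
                  mean_degree: float = 5.0) -> PPINetwork:
    """Connected, degree-heterogeneous network with planted communities.

    Nodes get a degree propensity (hubs drawn high, the rest from a
    light-tailed distribution); edge probabilities follow a Chung-Lu
    style product modulated by a within/between community factor.
    Components are stitched to the giant component afterwards, so the
    result is always connected. Community membership is stored as the
    ``community`` node attribute.
    """
    if n_nodes < 10:
        raise ValidationError("n_nodes must be >= 10")
    if not (0 <= hub_fraction < 1):
        raise ValidationError("hub_fraction must lie in [0, 1)")
    if community_count < 1 or community_count > n_nodes:
        raise ValidationError("community_count must lie in [1, n_nodes]")
    if not (mean_degree > 1):
        raise ValidationError("mean_degree must exceed 1")
    rng = np.random.default_rng(seed)
    names = [f"P{i:04d}" for i in range(n_nodes)]
    community = rng.integers(0, community_count, size=n_nodes)

    n_hubs = int(round(hub_fraction * n_nodes))
    theta = 1.0 + rng.exponential(scale=mean_degree - 1.0, size=n_nodes)
    if n_hubs > 0:
        hub_idx = rng.choice(n_nodes, size=n_hubs, replace=False)
        theta[hub_idx] = rng.uniform(25.0, 40.0, size=n_hubs)

    w_in, w_out = 1.0, 0.15
    mix_mean = (w_in + (community_count - 1) * w_out) / community_count
    same = community[:, None] == community[None, :]
    factor = np.where(same, w_in, w_out)
    P = np.outer(theta, theta) * factor / (theta.sum() * mix_mean)
    P = np.clip(P, 0.0, 0.95)

    upper = np.triu(rng.random((n_nodes, n_nodes)) < P, k=1)
    net = PPINetwork()
    for name in names:
        net.add_node(name)
    ii, jj = np.nonzero(upper)
    for i, j in zip(ii, jj):
        net.add_edge(names[i], names[j], 1.0)

    # stitch any stray components onto the largest one
    import networkx as nx
    comps = sorted(nx.connected_components(net.graph), key=len, reverse=True)
    giant = sorted(comps[0])
    for comp in comps[1:]:
        a = sorted(comp)[int(rng.integers(0, len(comp)))]
        b = giant[int(rng.integers(0, len(giant)))]
        net.add_edge(a, b, 1.0)
        giant = sorted(set(giant) | comp)

    for i, name in enumerate(names):
        net.graph.nodes[name]["community"] = int(community[i])
    return net


@dataclass(frozen=True)
class BenchmarkConfig:
    """Generative settings of a synthetic benchmark.

    Defaults give a desk-scale corpus with the conventional 10:1
    negative:positive imbalance, sequence lengths in [50, 300] (long
    enough for width-7 convolutions and width-9 pooling), and no label
    noise. ``noise_fraction`` > 0 plants that fraction of the negative
    set as mislabelled true interactions.
    """

    n_nodes: int = 120
    hub_fraction: float = 0.05
    community_count: int = 4
    mean_degree: float = 5.0
    negative_ratio: int = 10
    noise_fraction: float = 0.0
    seq_length_range: tuple = (50, 300)
    motif_length: int = 12
    motifs_per_seq: int = 3
    train_frac: float = 0.7
    val_frac: float = 0.15

    def __post_init__(self):
        if self.negative_ratio < 1:
            raise ValidationError("negative_ratio must be >= 1")
        if not (0 <= self.noise_fraction < 1):
            raise ValidationError("noise_fraction must lie in [0, 1)")
        lo, hi = self.seq_length_range
        if lo < self.motif_length or hi < lo:
            raise ValidationError("sequence length range must fit the motif")
        if not (0 < self.train_frac + self.val_frac < 1):
            raise ValidationError("train+val fractions must leave room for a test split")


@dataclass
class SyntheticBenchmark:
    """A complete generated corpus, reproducible from (config, seed)."""

    network: PPINetwork
    sequences: dict
    train: list
    val: list
    test: list
    config: BenchmarkConfig
    seed: int
    motifs: dict = field(default_factory=dict)
    communities: dict = field(default_factory=dict)
    planted_mislabels: list = field(default_factory=list)

    @property
    def all_examples(self) -> list:
        return self.train + self.val + self.test

    def class_ratio(self, split: str = "train") -> tuple[int, int]:
        pairs = getattr(self, split)
        pos = sum(ex.label for ex in pairs)
        return pos, len(pairs) - pos


def _random_sequence(rng: np.random.Generator, length: int) -> list:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def synth_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> SyntheticBenchmark:
    """Generate a full benchmark: network, motif-bearing sequences,
    labelled examples at the configured ratio, and disjoint splits."""
    cfg = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)

    net = synth_network(cfg.n_nodes, cfg.hub_fraction, cfg.community_count,
                        seed=int(rng.integers(0, 2**31)),
                        mean_degree=cfg.mean_degree)
    communities = {v: net.graph.nodes[v]["community"] for v in net.nodes}

    motifs = {}
    for c in range(cfg.community_count):
        motifs[c] = "".join(rng.choice(list(AMINO_ACIDS), size=cfg.motif_length))

    sequences = {}
    lo, hi = cfg.seq_length_range
    for v in sorted(net.nodes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        motif = motifs[communities[v]]
        for _ in range(cfg.motifs_per_seq):
            start = int(rng.integers(0, length - cfg.motif_length + 1))
            seq[start:start + cfg.motif_length] = list(motif)
        sequences[v] = "".join(seq)

    positives = sorted((min(a, b), max(a, b)) for a, b, _ in net.edges())
    n_neg_total = cfg.negative_ratio * len(positives)

    # planted mislabels: same-community non-edges with many common neighbours
    n_planted = int(round(cfg.noise_fraction * n_neg_total))
    planted = []
    if n_planted > 0:
        candidates = []
        nodes = sorted(net.nodes)
        for i, a in enumerate(nodes):
            na = net.neighbors(a)
            for b in nodes[i + 1:]:
                if net.has_edge(a, b) or communities[a] != communities[b]:
                    continue
                ncommon = len(na & net.neighbors(b))
                if ncommon >= 1:
                    candidates.append((ncommon, a, b))
        if len(candidates) < n_planted:
            raise ValidationError(
                f"cannot plant {n_planted} mislabels: only {len(candidates)} "
                "same-community non-edges with common neighbours exist"
            )
        order = sorted(range(len(candidates)),
                       key=lambda i: (-candidates[i][0], candidates[i][1], candidates[i][2]))
        planted = [(candidates[i][1], candidates[i][2]) for i in order[:n_planted]]

    # sample uniform negatives avoiding both true edges and planted pairs,
    # then trim to the exact target count
    avoid = positives + planted
    n_random_neg = n_neg_total - n_planted
    ratio = -(-n_random_neg // len(avoid))  # ceil
    negatives = sample_negatives(net.nodes, avoid, ratio,
                                 seed=int(rng.integers(0, 2**31)))
    negatives = negatives[:n_random_neg]

    examples = (
        [ExamplePair(a, b, 1) for a, b in positives]
        + [ExamplePair(a, b, 0) for a, b in negatives]
        + [ExamplePair(a, b, 0) for a, b in planted]
    )

    # stratified split, pair-disjoint by construction; planted mislabels
    # go to the training split only (they model unassayed interactions
    # corrupting the supervision), so held-out labels stay truthful
    planted_keys = {frozenset(p) for p in planted}
    train, val, test = [], [], []
    for label in (1, 0):
        group = [ex for ex in examples
                 if ex.label == label and ex.key not in planted_keys]
        idx = rng.permutation(len(group))
        n_train = int(round(cfg.train_frac * len(group)))
        n_val = int(round(cfg.val_frac * len(group)))
        for k, i in enumerate(idx):
            (train if k < n_train else val if k < n_train + n_val else test).append(group[i])
    train.extend(ex for ex in examples if ex.key in planted_keys)

    return SyntheticBenchmark(
        network=net, sequences=sequences, train=train, val=val, test=test,
        config=cfg, seed=seed, motifs=motifs, communities=communities,
        planted_mislabels=[tuple(p) for p in planted],
    )


def motif_cooccurrence_scores(benchmark: SyntheticBenchmark, pairs) -> np.ndarray:
    """Trivial sequence baseline: count motif types present in both
    sequences of a pair. Used to certify that the benchmark carries
    learnable sequence signal."""
    scores = []
    for ex in pairs:
        a, b = (ex.id_a, ex.id_b) if isinstance(ex, ExamplePair) else ex
        sa, sb = benchmark.sequences[a], benchmark.sequences[b]
        scores.append(sum(1 for m in benchmark.motifs.values() if m in sa and m in sb))
    return np.array(scores, dtype=float)


def write_benchmark(benchmark: SyntheticBenchmark, out_dir) -> None:
    """Write the benchmark bundle: FASTA, edge list, split tables and a
    JSON manifest sufficient to regenerate it."""
    from .io import write_edge_list, write_fasta, write_pairs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "sequences.fasta", benchmark.sequences)
    write_edge_list(out / "network.tsv", benchmark.network)
    for split in ("train", "val", "test"):
        write_pairs(out / f"{split}.tsv", getattr(benchmark, split))
    manifest = {
        "config": asdict(benchmark.config),
        "seed": benchmark.seed,
        "n_nodes": benchmark.network.n_nodes,
        "n_edges": benchmark.network.n_edges,
        "splits": {s: len(getattr(benchmark, s)) for s in ("train", "val", "test")},
        "class_ratio_train": benchmark.class_ratio("train"),
        "n_planted_mislabels": len(benchmark.planted_mislabels),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
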