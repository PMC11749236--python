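"""Seeded synthetic data: planted multi-level hierarchies, channelized
affinity graphs, GO-like flat labels and gene-level burden signals.

Everything regenerates bit-identically from (spec, seed), so the whole
pipeline is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graphio import LevelGraph, N_CHANNELS
from .hilander import LabelPartition
from .hisig import SignalTrack
from .treeops import Hierarchy


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 300
    branching: tuple[int, ...] = (20, 5)  # per-level cluster counts, fine -> coarse
    feature_dim: int = 32
    within_sd: float = 0.2
    between_sd: float = 1.0
    p_in: float = 0.9
    p_out: float = 0.02
    mu_in: float = 0.8
    mu_out: float = 0.1
    channel_sd: float = 0.1
    label_level: int = 1
    planted_systems: int = 3
    effect_size: float = 3.0
    base_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "branching", tuple(self.branching))
        if not self.branching or min(self.branching) < 1:
            raise ValueError("branching must list positive cluster counts")
        if any(a < b for a, b in zip(self.branching, self.branching[1:])):
            raise ValueError("branching sizes must be non-increasing upward")
        if self.branching[0] > self.n_genes:
            raise ValueError("more leaf clusters than genes")
        for prob in (self.p_in, self.p_out):
            if not (0.0 <= prob <= 1.0):
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.mu_in <= self.mu_out:
            raise ValueError("mu_in must exceed mu_out")
        if self.within_sd >= self.between_sd:
            raise ValueError("within_sd must be below between_sd")
        if not (1 <= self.label_level <= len(self.branching)):
            raise ValueError("label_level out of range")


@dataclass(frozen=True)
class SyntheticDataset:
    spec: SyntheticSpec
    graph: LevelGraph
    labels: LabelPartition
    truth: Hierarchy
    level_partitions: tuple[dict, ...]  # gene -> planted cluster id, per level
    tracks: dict  # name -> SignalTrack
    planted_ids: tuple[str, ...]

    def partition_at(self, level: int) -> dict:
        """Planted gene partition at hierarchy level (1-based)."""
        return dict(self.level_partitions[level - 1])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Sample a planted hierarchy, hierarchical-Gaussian features,
    channelized edges, flat labels and burden tracks."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    n = spec.n_genes
    levels = list(spec.branching)
    depth = len(levels)

    # ancestry: cluster index of each gene at every level (fine -> coarse)
    parent_of: list[np.ndarray] = []  # parent_of[l][c] = parent cluster at level l+1
    for l in range(depth - 1):
        parent_of.append(rng.integers(0, levels[l + 1], size=levels[l]))
    # balanced assignment of genes to leaf clusters, then shuffled
    leaf_assign = np.sort(np.arange(n) % levels[0])
    rng.shuffle(leaf_assign)
    assigns = [leaf_assign]
    for l in range(depth - 1):
        assigns.append(parent_of[l][assigns[-1]])

    # hierarchical Gaussian cluster means (coarse -> fine)
    means_by_level: list[np.ndarray] = [None] * depth  # type: ignore[list-item]
    means_by_level[depth - 1] = rng.normal(
        0.0, spec.between_sd, size=(levels[-1], spec.feature_dim)
    )
    for l in range(depth - 2, -1, -1):
        offsets = rng.normal(0.0, spec.between_sd, size=(levels[l], spec.feature_dim))
        means_by_level[l] = means_by_level[l + 1][parent_of[l]] + offsets
    features = means_by_level[0][leaf_assign] + rng.normal(
        0.0, spec.within_sd, size=(n, spec.feature_dim)
    )

    # edges: Bernoulli(p_in) within leaf clusters, Bernoulli(p_out) between
    same = leaf_assign[:, None] == leaf_assign[None, :]
    iu, ju = np.triu_indices(n, k=1)
    within = same[iu, ju]
    draw = rng.random(iu.shape[0])
    keep = np.where(within, draw < spec.p_in, draw < spec.p_out)
    eu, ev = iu[keep], ju[keep]
    mu = np.where(within[keep], spec.mu_in, spec.mu_out)
    channels = np.clip(
        rng.normal(mu[:, None], spec.channel_sd, size=(eu.shape[0], N_CHANNELS)),
        0.0,
        None,
    )
    order = np.lexsort((ev, eu))
    edges = np.column_stack([eu, ev])[order]
    channels = channels[order]
    graph = LevelGraph(
        level=0,
        node_ids=tuple(genes),
        node_features=features,
        edges=edges,
        edge_attr=channels,
    )

    # planted hierarchy and per-level partitions
    children: dict[str, list[str]] = {}
    sys_name = lambda l, c: f"T{l}-{c}"  # noqa: E731
    for l in range(1, depth + 1):
        for c in range(levels[l - 1]):
            children[sys_name(l, c)] = []
    for i, g in enumerate(genes):
        children[sys_name(1, int(leaf_assign[i]))].append(g)
    for l in range(1, depth):
        for c in range(levels[l - 1]):
            children[sys_name(l + 1, int(parent_of[l - 1][c]))].append(sys_name(l, c))
    # drop empty systems (possible for tiny n) and systems covering < 2 genes
    def covered(sys_id: str) -> set:
        out: set = set()
        for kid in children.get(sys_id, []):
            if kid in children:
                out |= covered(kid)
            else:
                out.add(kid)
        return out

    for sys_id in sorted(children, reverse=True):
        if len(covered(sys_id)) < 2:
            for kids in children.values():
                if sys_id in kids:
                    kids.remove(sys_id)
            del children[sys_id]
    truth = Hierarchy(genes=tuple(genes), children=children)

    level_partitions = tuple(
        {g: sys_name(l + 1, int(assigns[l][i])) for i, g in enumerate(genes)}
        for l in range(depth)
    )
    labels = LabelPartition(
        assignments=level_partitions[spec.label_level - 1], branch="GO"
    )

    # planted burden systems: a seeded choice among leaf-level systems
    leaf_systems = sorted(s for s in children if s.startswith("T1-"))
    n_plant = min(spec.planted_systems, len(leaf_systems))
    planted = tuple(
        sorted(rng.choice(len(leaf_systems), size=n_plant, replace=False).tolist())
    )
    planted_ids = tuple(leaf_systems[i] for i in planted)
    tracks = simulate_signals(
        truth,
        planted_ids,
        effect_size=spec.effect_size,
        base_rate=spec.base_rate,
        seed=spec.seed + 1,
    )
    return SyntheticDataset(
        spec=spec,
        graph=graph,
        labels=labels,
        truth=truth,
        level_partitions=level_partitions,
        tracks=tracks,
        planted_ids=planted_ids,
    )


def simulate_signals(
    hierarchy: Hierarchy,
    planted: Sequence[str],
    effect_size: float = 3.0,
    base_rate: float = 1.0,
    seed: int = 0,
) -> dict[str, SignalTrack]:
    """Count-like (Poisson) and z-like (Gaussian) burden tracks, elevated on
    the genes of the planted systems."""
    unknown = set(planted) - set(hierarchy.children)
    if unknown:
        raise ValueError(f"planted ids not in hierarchy: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genes = sorted(hierarchy.genes)
    burdened: set = set()
    for sys_id in planted:
        burdened |= hierarchy.gene_set(sys_id)
    flag = np.array([g in burdened for g in genes], dtype=float)
    counts = rng.poisson(base_rate + effect_size * flag).astype(float)
    zvals = rng.normal(effect_size * flag, 1.0)
    return {
        "counts": SignalTrack(
            name="counts", values=dict(zip(genes, counts)), transform="none"
        ),
        "zscores": SignalTrack(
            name="zscores", values=dict(zip(genes, zvals)), transform="abs"
        ),
    }
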