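"""Supervised hierarchical graph clustering.

A message-passing encoder scores each edge with a linkage probability and
each node with a density; decoding keeps, per node, at most one edge toward
a higher-density neighbor, and connected components of the kept edges become
the clusters.  Clusters aggregate into the next-level graph (mean + peak
feature blocks, mutual-kNN cosine edges) and the procedure iterates into a
hierarchy.

The model is trained against flattened GO-style labels: edge target 1 iff
the endpoints share a class, node density target the weighted same-class
fraction of the neighborhood.  Implementation is pure numpy (hand-written
backprop + Adam); at the graph sizes this package targets a training run
takes seconds on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .graphio import LevelGraph, partition_from_components
from .treeops import Hierarchy

Array = np.ndarray


# ---------------------------------------------------------------------------
# labels and splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelPartition:
    """Flat supervision: gene id -> single class id."""

    assignments: Mapping[str, str]
    branch: str = "GO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))

    @property
    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cls in self.assignments.values():
            sizes[cls] = sizes.get(cls, 0) + 1
        return sizes

    def __len__(self) -> int:
        return len(self.assignments)


def flatten_go_labels(
    annotations: Mapping[str, set],
    branch: str = "GO",
    min_size: int = 10,
    max_size: int = 500,
) -> LabelPartition:
    """Collapse multi-term annotations to one class per gene.

    Terms whose member count falls outside [min_size, max_size] are dropped;
    each gene is labeled by its smallest surviving term (ties by term id);
    genes with no surviving term are excluded.
    """
    if not annotations:
        raise ValueError("empty annotation mapping")
    term_sizes: dict[str, int] = {}
    for terms in annotations.values():
        for t in terms:
            term_sizes[t] = term_sizes.get(t, 0) + 1
    surviving = {t for t, s in term_sizes.items() if min_size <= s <= max_size}
    if not surviving:
        raise ValueError(
            f"no GO term has between {min_size} and {max_size} members; widen the bounds"
        )
    assignments: dict[str, str] = {}
    for gene, terms in annotations.items():
        candidates = sorted(terms & surviving, key=lambda t: (term_sizes[t], t))
        if candidates:
            assignments[gene] = candidates[0]
    return LabelPartition(assignments=assignments, branch=branch)


def split_nodes(
    node_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[set, set, set]:
    """Random disjoint train/val/test id sets with rounded ratio shares."""
    if len(node_ids) < 3:
        raise ValueError("need at least 3 nodes to split")
    if min(ratios) <= 0 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    ids = sorted(node_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(n * ratios[0]))
    n_val = int(round(n * ratios[1]))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    train = {ids[i] for i in perm[:n_train]}
    val = {ids[i] for i in perm[n_train : n_train + n_val]}
    test = {ids[i] for i in perm[n_train + n_val :]}
    return train, val, test


# ---------------------------------------------------------------------------
# model configuration and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    mpgnn_layers: int = 2
    hidden_dim: int = 256
    k: int = 10
    p_tau: float = 0.5
    max_levels: int = 10
    loss_weights: tuple[float, float] = (1.0, 1.0)
    epochs: int = 100
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_tau <= 1.0):
            raise ValueError("p_tau must lie in [0, 1]")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.mpgnn_layers < 0 or self.hidden_dim < 1 or self.k < 1:
            raise ValueError("mpgnn_layers >= 0, hidden_dim >= 1, k >= 1 required")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs >= 0 and learning_rate > 0 required")

    def as_dict(self) -> dict:
        return {
            "mpgnn_layers": self.mpgnn_layers,
            "hidden_dim": self.hidden_dim,
            "k": self.k,
            "p_tau": self.p_tau,
            "max_levels": self.max_levels,
            "loss_weights": list(self.loss_weights),
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ModelConfig":
        d = dict(d)
        if "loss_weights" in d:
            d["loss_weights"] = tuple(d["loss_weights"])
        return ModelConfig(**d)


def _init_encoder(rng: np.random.Generator, in_dim: int, edge_dim: int, cfg: ModelConfig) -> dict:
    h = cfg.hidden_dim

    def glorot(fan_in: int, fan_out: int) -> Array:
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    params = {"W_in": glorot(in_dim, h), "b_in": np.zeros(h)}
    for l in range(cfg.mpgnn_layers):
        params[f"W_msg{l}"] = glorot(2 * h + edge_dim, h)
        params[f"b_msg{l}"] = np.zeros(h)
        params[f"W_upd{l}"] = glorot(2 * h, h)
        params[f"b_upd{l}"] = np.zeros(h)
    params["W_link"] = glorot(4 * h, 1)[:, 0]
    params["b_link"] = np.zeros(1)
    params["W_dens"] = glorot(h, 1)[:, 0]
    params["b_dens"] = np.zeros(1)
    return params


@dataclass
class LinkageScores:
    """Per-edge linkage probabilities and per-node densities, aligned with a
    LevelGraph's edge/node order."""

    edge_prob: Array
    node_density: Array

    def prob(self, graph: LevelGraph, u: str, v: str) -> float:
        iu, iv = graph.node_ids.index(u), graph.node_ids.index(v)
        if iu > iv:
            iu, iv = iv, iu
        for e, (a, b) in enumerate(graph.edges):
            if a == iu and b == iv:
                return float(self.edge_prob[e])
        raise KeyError((u, v))

    def density(self, graph: LevelGraph, u: str) -> float:
        return float(self.node_density[graph.node_ids.index(u)])


@dataclass
class TrainedModel:
    config: ModelConfig
    base: dict
    upper: dict
    history: list = field(default_factory=list)

    def encoder_for(self, graph: LevelGraph) -> dict:
        return self.base if graph.level == 0 else self.upper

    def save(self, path) -> None:
        arrays = {}
        for prefix, params in (("base", self.base), ("upper", self.upper)):
            for k, v in params.items():
                arrays[f"{prefix}.{k}"] = v
        meta = json.dumps({"config": self.config.as_dict(), "history": self.history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        base, upper = {}, {}
        for key in data.files:
            if key == "__meta__":
                continue
            prefix, name = key.split(".", 1)
            (base if prefix == "base" else upper)[name] = data[key]
        return TrainedModel(
            config=ModelConfig.from_dict(meta["config"]),
            base=base,
            upper=upper,
            history=meta["history"],
        )


def init_model(cfg: ModelConfig, feature_dim: int) -> TrainedModel:
    """Seeded parameter initialization; the upper encoder consumes the
    mean ⊕ peak concatenation (2x width) with scalar edge weights."""
    rng = np.random.default_rng(cfg.seed)
    base = _init_encoder(rng, feature_dim, 5, cfg)
    upper = _init_encoder(rng, 2 * feature_dim, 1, cfg)
    return TrainedModel(config=cfg, base=base, upper=upper)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _forward(params: dict, X: Array, edges: Array, eattr: Array, n_layers: int) -> dict:
    n = X.shape[0]
    h = params["b_in"].shape[0]
    Z0 = X @ params["W_in"] + params["b_in"]
    H = np.maximum(Z0, 0.0)
    cache: dict = {"X": X, "Z0": Z0, "layers": []}
    if edges.shape[0]:
        src = np.concatenate([edges[:, 0], edges[:, 1]])
        dst = np.concatenate([edges[:, 1], edges[:, 0]])
        E2 = np.vstack([eattr, eattr])
    else:
        src = np.empty(0, dtype=np.int64)
        dst = np.empty(0, dtype=np.int64)
        E2 = np.empty((0, eattr.shape[1] if eattr.ndim == 2 else 1))
    deg = np.bincount(dst, minlength=n).astype(float)
    safe_deg = np.maximum(deg, 1.0)
    cache.update(src=src, dst=dst, deg=safe_deg)
    for l in range(n_layers):
        Min = np.hstack([H[src], H[dst], E2])
        Zm = Min @ params[f"W_msg{l}"] + params[f"b_msg{l}"]
        M = np.maximum(Zm, 0.0)
        S = np.zeros((n, h))
        np.add.at(S, dst, M)
        agg = S / safe_deg[:, None]
        Uin = np.hstack([H, agg])
        Zu = Uin @ params[f"W_upd{l}"] + params[f"b_upd{l}"]
        H_next = np.maximum(Zu, 0.0)
        cache["layers"].append({"H": H, "Min": Min, "Zm": Zm, "Uin": Uin, "Zu": Zu})
        H = H_next
    cache["H_final"] = H
    return cache


def _heads(params: dict, H: Array, edges: Array) -> tuple[Array, Array, dict]:
    if edges.shape[0]:
        hu, hv = H[edges[:, 0]], H[edges[:, 1]]
        F = np.hstack([hu, hv, np.abs(hu - hv), hu * hv])
        zl = F @ params["W_link"] + params["b_link"][0]
    else:
        hu = hv = np.empty((0, H.shape[1]))
        F = np.empty((0, 4 * H.shape[1]))
        zl = np.empty(0)
    p = 1.0 / (1.0 + np.exp(-zl))
    zd = H @ params["W_dens"] + params["b_dens"][0]
    d = np.tanh(zd)
    return p, d, {"F": F, "hu": hu, "hv": hv, "zl": zl, "zd": zd, "p": p, "d": d}


def _loss_and_grads(
    params: dict,
    cache: dict,
    head_cache: dict,
    edges: Array,
    edge_target: Array,
    dens_target: Array,
    edge_mask: Array,
    node_mask: Array,
    loss_weights: tuple[float, float],
    n_layers: int,
) -> tuple[float, dict]:
    w1, w2 = loss_weights
    p, d = head_cache["p"], head_cache["d"]
    H = cache["H_final"]
    n_e = max(float(edge_mask.sum()), 1.0)
    n_v = max(float(node_mask.sum()), 1.0)
    eps = 1e-12
    bce = -(edge_target * np.log(p + eps) + (1 - edge_target) * np.log(1 - p + eps))
    loss = w1 * float((bce * edge_mask).sum()) / n_e
    loss += w2 * float((((d - dens_target) ** 2) * node_mask).sum()) / n_v

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dH = np.zeros_like(H)

    # linkage head
    if edges.shape[0]:
        dzl = w1 * (p - edge_target) * edge_mask / n_e
        F, hu, hv = head_cache["F"], head_cache["hu"], head_cache["hv"]
        grads["W_link"] = F.T @ dzl
        grads["b_link"] = np.array([dzl.sum()])
        h = H.shape[1]
        wl = params["W_link"]
        wa, wb, wc, wd = wl[:h], wl[h : 2 * h], wl[2 * h : 3 * h], wl[3 * h :]
        sgn = np.sign(hu - hv)
        dhu = np.outer(dzl, wa) + np.outer(dzl, wc) * sgn + np.outer(dzl, wd) * hv
        dhv = np.outer(dzl, wb) - np.outer(dzl, wc) * sgn + np.outer(dzl, wd) * hu
        np.add.at(dH, edges[:, 0], dhu)
        np.add.at(dH, edges[:, 1], dhv)

    # density head
    dd = w2 * 2.0 * (d - dens_target) * node_mask / n_v
    dzd = dd * (1.0 - d**2)
    grads["W_dens"] = H.T @ dzd
    grads["b_dens"] = np.array([dzd.sum()])
    dH += np.outer(dzd, params["W_dens"])

    # message-passing layers, reverse order
    src, dst, deg = cache["src"], cache["dst"], cache["deg"]
    for l in range(n_layers - 1, -1, -1):
        lc = cache["layers"][l]
        h = dH.shape[1]
        dZu = dH * (lc["Zu"] > 0)
        grads[f"W_upd{l}"] = lc["Uin"].T @ dZu
        grads[f"b_upd{l}"] = dZu.sum(axis=0)
        dUin = dZu @ params[f"W_upd{l}"].T
        dH_prev = dUin[:, :h].copy()
        dagg = dUin[:, h:]
        if src.shape[0]:
            dS = dagg / deg[:, None]
            dM = dS[dst]
            dZm = dM * (lc["Zm"] > 0)
            grads[f"W_msg{l}"] = lc["Min"].T @ dZm
            grads[f"b_msg{l}"] = dZm.sum(axis=0)
            dMin = dZm @ params[f"W_msg{l}"].T
            np.add.at(dH_prev, src, dMin[:, :h])
            np.add.at(dH_prev, dst, dMin[:, h : 2 * h])
        dH = dH_prev

    dZ0 = dH * (cache["Z0"] > 0)
    grads["W_in"] = cache["X"].T @ dZ0
    grads["b_in"] = dZ0.sum(axis=0)
    return loss, grads


def mpgnn_encode(graph: LevelGraph, model: TrainedModel) -> Array:
    """Final node embeddings (n x hidden_dim) for a graph at any level."""
    params = model.encoder_for(graph)
    X = graph.encoder_input()
    if X.shape[1] != params["W_in"].shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match encoder input width "
            f"{params['W_in'].shape[0]}"
        )
    cache = _forward(params, X, graph.edges, graph.edge_attr, model.config.mpgnn_layers)
    return cache["H_final"]


def score_graph(graph: LevelGraph, model: TrainedModel) -> LinkageScores:
    """Linkage probabilities for every edge and a density for every node."""
    params = model.encoder_for(graph)
    X = graph.encoder_input()
    if X.shape[1] != params["W_in"].shape[0]:
        raise ValueError("feature width does not match encoder input width")
    cache = _forward(params, X, graph.edges, graph.edge_attr, model.config.mpgnn_layers)
    p, d, _ = _heads(params, cache["H_final"], graph.edges)
    return LinkageScores(edge_prob=p, node_density=d)


# ---------------------------------------------------------------------------
# supervision targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Targets:
    edge_target: Array  # {0,1} per canonical edge
    density_target: Array  # [-1,1] per node
    edge_mask: Array  # 1 where both endpoints labeled
    node_mask: Array  # 1 where the node is labeled


def _edge_strength(graph: LevelGraph) -> Array:
    """Scalar weight per edge: mean channel score at level 0, similarity above."""
    if graph.edge_attr.shape[0] == 0:
        return np.empty(0)
    return graph.edge_attr.mean(axis=1) if graph.level == 0 else graph.edge_attr[:, 0]


def ground_truth_targets(
    graph: LevelGraph, labels: Mapping[str, str] | LabelPartition
) -> Targets:
    """Edge target 1 iff endpoints share a class; node density target the
    edge-strength-weighted same-class fraction of the neighborhood (+1 same,
    -1 different; 0 for neighborless nodes).  Unlabeled nodes are masked."""
    if isinstance(labels, LabelPartition):
        labels = labels.assignments
    n = graph.n_nodes
    node_cls = np.array(
        [labels.get(nid) for nid in graph.node_ids], dtype=object
    )
    node_mask = np.array([c is not None for c in node_cls], dtype=float)
    strengths = _edge_strength(graph)
    edge_target = np.zeros(graph.n_edges)
    edge_mask = np.zeros(graph.n_edges)
    num = np.zeros(n)
    den = np.zeros(n)
    for e, (a, b) in enumerate(graph.edges):
        ca, cb = node_cls[a], node_cls[b]
        if ca is None or cb is None:
            continue
        edge_mask[e] = 1.0
        same = 1.0 if ca == cb else -1.0
        edge_target[e] = 1.0 if same > 0 else 0.0
        s = max(float(strengths[e]), 0.0)
        num[a] += s * same
        num[b] += s * same
        den[a] += s
        den[b] += s
    density = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return Targets(
        edge_target=edge_target,
        density_target=density,
        edge_mask=edge_mask,
        node_mask=node_mask,
    )


# ---------------------------------------------------------------------------
# decoding and aggregation
# ---------------------------------------------------------------------------


def decode_level(
    graph: LevelGraph, scores: LinkageScores, p_tau: float
) -> dict[str, str]:
    """Keep, per node, its highest-probability edge toward a neighbor of >=
    density (prob >= p_tau required; ties by smaller neighbor id); clusters
    are connected components of the kept edges.  Returns node id -> cluster
    id (smallest member id)."""
    prob = np.asarray(scores.edge_prob, dtype=float)
    dens = np.asarray(scores.node_density, dtype=float)
    if prob.shape[0] != graph.n_edges or dens.shape[0] != graph.n_nodes:
        raise ValueError("scores do not cover the graph")
    adj = graph.adjacency()
    kept: set[int] = set()
    for i in range(graph.n_nodes):
        best: Optional[tuple[float, str, int]] = None
        for j, e in adj[i]:
            if prob[e] < p_tau or dens[j] < dens[i]:
                continue
            cand = (-prob[e], graph.node_ids[j], e)
            if best is None or cand < best:
                best = cand
        if best is not None:
            kept.add(best[2])
    # union-find over kept edges
    parent = list(range(graph.n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in kept:
        a, b = graph.edges[e]
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    comp_min: dict[int, str] = {}
    roots = [find(i) for i in range(graph.n_nodes)]
    for i, r in enumerate(roots):
        nid = graph.node_ids[i]
        if r not in comp_min or nid < comp_min[r]:
            comp_min[r] = nid
    return {graph.node_ids[i]: comp_min[roots[i]] for i in range(graph.n_nodes)}


def _mutual_knn_edges(features: Array, k: int) -> tuple[Array, Array]:
    """Mutual k-nearest-neighbor pairs under cosine similarity.

    Returns (edges (m,2) with u < v, weights (m,))."""
    n = features.shape[0]
    if n < 2:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    norms = np.linalg.norm(features, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = features / safe[:, None]
    sim = unit @ unit.T
    np.fill_diagonal(sim, -np.inf)
    kk = min(k, n - 1)
    # stable ranking: by descending similarity, then ascending index
    order = np.lexsort((np.arange(n)[None, :].repeat(n, 0), -sim), axis=1)
    knn = order[:, :kk]
    neighbor_sets = [set(row.tolist()) for row in knn]
    edges = []
    weights = []
    for i in range(n):
        for j in knn[i]:
            j = int(j)
            if j > i and i in neighbor_sets[j]:
                edges.append((i, j))
                weights.append(sim[i, j])
    if not edges:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    e = np.array(edges, dtype=np.int64)
    w = np.array(weights)
    order = np.lexsort((e[:, 1], e[:, 0]))
    return e[order], w[order]


def aggregate_level(
    graph: LevelGraph,
    clusters: Mapping[str, set],
    scores: LinkageScores,
    k: int = 10,
) -> LevelGraph:
    """Collapse each cluster into one node of the next-level graph.

    The new mean feature is the average of member mean features; the peak
    feature is the mean feature of the member with maximal density (ties by
    smaller id).  Singleton clusters pass through with their node id and
    features unchanged.  New edges are mutual k-nearest-neighbor pairs under
    cosine similarity on mean features, with the similarity as weight."""
    covered = set()
    for m in clusters.values():
        covered |= set(m)
    if covered != set(graph.node_ids):
        raise ValueError("clusters do not partition the graph nodes")
    if sum(len(m) for m in clusters.values()) != graph.n_nodes:
        raise ValueError("clusters overlap")
    index = {nid: i for i, nid in enumerate(graph.node_ids)}
    dens = np.asarray(scores.node_density, dtype=float)
    new_ids = []
    mean_rows = []
    peak_rows = []
    members: dict[str, frozenset] = {}
    for cid in sorted(clusters):
        group = sorted(clusters[cid])
        rows = [index[g] for g in group]
        if len(group) == 1:
            nid = group[0]
            mean = graph.node_features[rows[0]]
            peak = (
                graph.peak_features[rows[0]]
                if graph.peak_features is not None
                else graph.node_features[rows[0]]
            )
        else:
            nid = cid
            mean = graph.node_features[rows].mean(axis=0)
            # maximal density; ties resolved toward the smaller node id
            best = max(float(dens[r]) for r in rows)
            tied = [r for r in rows if dens[r] == best]
            peak_idx = min(tied, key=lambda r: graph.node_ids[r])
            peak = graph.node_features[peak_idx]
        new_ids.append(nid)
        mean_rows.append(mean)
        peak_rows.append(peak)
        members[nid] = frozenset().union(
            *(graph.members[g] for g in group)
        )
    order = np.argsort(np.asarray(new_ids, dtype=object))
    new_ids = [new_ids[i] for i in order]
    mean_arr = np.array([mean_rows[i] for i in order])
    peak_arr = np.array([peak_rows[i] for i in order])
    edges, weights = _mutual_knn_edges(mean_arr, k)
    return LevelGraph(
        level=graph.level + 1,
        node_ids=tuple(new_ids),
        node_features=mean_arr,
        peak_features=peak_arr,
        edges=edges,
        edge_attr=weights.reshape(-1, 1),
        members=members,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _adam_step(params, grads, state, lr, t, b1=0.9, b2=0.999, eps=1e-8):
    for key in params:
        g = grads[key]
        m, v = state[key]
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        state[key] = (m, v)
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        params[key] = params[key] - lr * mhat / (np.sqrt(vhat) + eps)


def _induced_subgraph(graph: LevelGraph, keep: set) -> LevelGraph:
    idx = [i for i, nid in enumerate(graph.node_ids) if nid in keep]
    remap = {old: new for new, old in enumerate(idx)}
    sel = [
        e
        for e, (a, b) in enumerate(graph.edges)
        if int(a) in remap and int(b) in remap
    ]
    edges = (
        np.array([[remap[int(a)], remap[int(b)]] for a, b in graph.edges[sel]], dtype=np.int64)
        if sel
        else np.empty((0, 2), dtype=np.int64)
    )
    attr = graph.edge_attr[sel] if sel else np.empty((0, graph.edge_attr.shape[1]))
    ids = tuple(graph.node_ids[i] for i in idx)
    return LevelGraph(
        level=graph.level,
        node_ids=ids,
        node_features=graph.node_features[idx],
        peak_features=None if graph.peak_features is None else graph.peak_features[idx],
        edges=edges,
        edge_attr=attr,
        members={nid: graph.members[nid] for nid in ids},
    )


def _train_encoder(
    params: dict,
    graph: LevelGraph,
    targets: Targets,
    cfg: ModelConfig,
    phase: str,
    history: list,
    val_hook: Optional[Callable[[dict], float]] = None,
) -> None:
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    X = graph.encoder_input()
    for epoch in range(1, cfg.epochs + 1):
        cache = _forward(params, X, graph.edges, graph.edge_attr, cfg.mpgnn_layers)
        p, d, head_cache = _heads(params, cache["H_final"], graph.edges)
        loss, grads = _loss_and_grads(
            params,
            cache,
            head_cache,
            graph.edges,
            targets.edge_target,
            targets.density_target,
            targets.edge_mask,
            targets.node_mask,
            cfg.loss_weights,
            cfg.mpgnn_layers,
        )
        _adam_step(params, grads, state, cfg.learning_rate, epoch)
        record = {"phase": phase, "epoch": epoch, "loss": loss}
        if val_hook is not None:
            record["val_fp"] = val_hook(params)
        history.append(record)


def _majority_label(
    member_genes: frozenset, labels: Mapping[str, str]
) -> Optional[str]:
    counts: dict[str, int] = {}
    for g in member_genes:
        cls = labels.get(g)
        if cls is not None:
            counts[cls] = counts.get(cls, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda c: counts[c])


def train_model(
    graph: LevelGraph,
    labels: LabelPartition,
    split: tuple[set, set, set],
    config: ModelConfig,
    upper_labels: Optional[Sequence[LabelPartition]] = None,
) -> TrainedModel:
    """Train the linkage/density model.

    The base encoder is fit on the training-node induced subgraph of the
    level-0 graph (loss restricted to edges internal to the training set).
    When ``upper_labels`` (coarser gene-level partitions, one per additional
    hierarchy level) are supplied, the training subgraph is decoded and
    aggregated and the shared upper-level encoder is fit against majority
    classes of the coarser partition — enabling learned merges above level 1.

    With ``config.epochs == 0`` the returned parameters equal the seeded
    initialization.
    """
    train_ids, val_ids, _ = split
    model = init_model(config, graph.node_features.shape[1])
    labeled = set(labels.assignments)
    sub = _induced_subgraph(graph, set(train_ids) & labeled)
    if sub.n_edges == 0:
        raise ValueError("training-node induced subgraph has no edges")
    targets = ground_truth_targets(sub, labels)

    def val_fp(params: dict) -> float:
        from .clustereval import pairwise_f

        probe = TrainedModel(config=config, base=params, upper=model.upper)
        assignment = decode_level(graph, score_graph(graph, probe), config.p_tau)
        eval_ids = set(val_ids) & labeled
        if not eval_ids:
            return float("nan")
        pred = {g: assignment[g] for g in eval_ids}
        true = {g: labels.assignments[g] for g in eval_ids}
        return pairwise_f(pred, true)[2]

    _train_encoder(model.base, sub, targets, config, "base", model.history, val_fp)

    if upper_labels:
        current = sub
        for depth, part in enumerate(upper_labels, start=1):
            scores = score_graph(current, model)
            assignment = decode_level(current, scores, config.p_tau)
            clusters = partition_from_components(assignment)
            if all(len(m) == 1 for m in clusters.values()):
                break
            current = aggregate_level(current, clusters, scores, k=config.k)
            node_labels = {}
            for nid in current.node_ids:
                cls = _majority_label(current.members[nid], part.assignments)
                if cls is not None:
                    node_labels[nid] = cls
            if current.n_edges == 0 or not node_labels:
                break
            upper_targets = ground_truth_targets(current, node_labels)
            if upper_targets.edge_mask.sum() == 0:
                break
            _train_encoder(
                model.upper, current, upper_targets, config, f"upper{depth}", model.history
            )
    return model


# ---------------------------------------------------------------------------
# hierarchy inference
# ---------------------------------------------------------------------------


def infer_hierarchy(
    graph: LevelGraph,
    model: Optional[TrainedModel],
    config: Optional[ModelConfig] = None,
    scorer: Optional[Callable[[LevelGraph], LinkageScores]] = None,
) -> Hierarchy:
    """Iterate score -> decode -> aggregate into a hierarchy of systems.

    ``scorer`` overrides the model (used e.g. for oracle-scored decoding).
    Systems are created only for clusters of size >= 2; singleton clusters
    pass through unchanged.  Iteration stops when a level produces no
    non-singleton cluster or after ``max_levels`` levels.
    """
    if scorer is None:
        if model is None:
            raise ValueError("either a model or a scorer is required")
        scorer = lambda g: score_graph(g, model)  # noqa: E731
    cfg = config or (model.config if model is not None else ModelConfig())
    current = graph
    children: dict[str, list[str]] = {}
    for level in range(1, cfg.max_levels + 1):
        if current.n_nodes < 2:
            break
        scores = scorer(current)
        assignment = decode_level(current, scores, cfg.p_tau)
        clusters = partition_from_components(assignment)
        merged = {cid: m for cid, m in clusters.items() if len(m) >= 2}
        if not merged:
            break
        renamed: dict[str, set] = {}
        sys_of: dict[str, str] = {}
        for idx, cid in enumerate(sorted(merged)):
            sys_id = f"S{level}-{idx}"
            renamed[sys_id] = set(merged[cid])
            sys_of[sys_id] = sys_id
            children[sys_id] = sorted(merged[cid])
        for cid, m in clusters.items():
            if len(m) == 1:
                only = next(iter(m))
                renamed[only] = {only}
        current = aggregate_level(current, renamed, scores, k=cfg.k)
    return Hierarchy(genes=graph.node_ids, children=children)


def oracle_scorer(
    level_partitions: Sequence[Mapping[str, str]],
) -> Callable[[LevelGraph], LinkageScores]:
    """Scorer that replays ground-truth targets instead of a model.

    ``level_partitions[l]`` is a gene-level partition used when scoring the
    graph at level ``l`` (each node's class = majority class of its member
    genes)."""

    def score(graph: LevelGraph) -> LinkageScores:
        part = level_partitions[min(graph.level, len(level_partitions) - 1)]
        node_labels = {}
        for nid in graph.node_ids:
            cls = _majority_label(graph.members[nid], part)
            if cls is not None:
                node_labels[nid] = cls
        t = ground_truth_targets(graph, node_labels)
        prob = np.where(t.edge_mask > 0, t.edge_target, 0.0)
        return LinkageScores(edge_prob=prob, node_density=t.density_target)

    return score
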