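"""Domain types and readers/writers for sequences, edge tables, feature
matrices and the per-level affinity-graph structure.

All tab-separated files carry one header row and are UTF-8.  Edge tables hold
five nonnegative association channels per protein pair::

    u  v  physical  mrna_coexp  prot_coexp  seq_sim  codep

Feature tables hold ``node_id`` followed by D float columns.  Matrices are
always ordered by the sorted node-id list so that outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

CHANNEL_NAMES = ("physical", "mrna_coexp", "prot_coexp", "seq_sim", "codep")
N_CHANNELS = len(CHANNEL_NAMES)

# residues allowed in input sequences: the 20 canonical letters plus X/B/Z/U
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid file with invalid content."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single FASTA entry."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be nonempty")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved.  Malformed headers,
    empty sequences and duplicate ids raise :class:`ParseError` naming the
    offending line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"line {header_line}: record {header!r} has an empty sequence")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ParseError(
                f"line {header_line}: record {header!r} contains invalid residues {sorted(bad)}"
            )
        name, _, desc = header.partition(" ")
        if name in seen:
            raise ParseError(f"line {header_line}: duplicate record id {name!r}")
        seen.add(name)
        records.append(ProteinRecord(id=name, sequence=seq, description=desc.strip()))

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence data before any header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


@dataclass(frozen=True)
class EdgeTable:
    """Canonicalized undirected edges with 5 nonnegative channel scores.

    Edges are stored with ``u < v`` lexicographically, without duplicates.
    """

    u: tuple[str, ...]
    v: tuple[str, ...]
    channels: np.ndarray  # (n_edges, 5)

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[1] != N_CHANNELS:
            raise ValidationError(f"channels must be (n, {N_CHANNELS}); got {ch.shape}")
        if ch.shape[0] != len(self.u) or len(self.u) != len(self.v):
            raise ValidationError("u, v and channels disagree on edge count")
        if not np.all(np.isfinite(ch)):
            raise ValidationError("non-finite channel score")
        if np.any(ch < 0):
            raise ValidationError("negative channel score")
        seen = set()
        for a, b in zip(self.u, self.v):
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            if a > b:
                raise ValidationError(f"edge ({a!r}, {b!r}) not canonical (u < v required)")
            if (a, b) in seen:
                raise ValidationError(f"duplicate edge ({a!r}, {b!r})")
            seen.add((a, b))
        ch.setflags(write=False)
        object.__setattr__(self, "channels", ch)

    def __len__(self) -> int:
        return len(self.u)

    @staticmethod
    def from_rows(rows: Iterable[tuple[str, str, Sequence[float]]]) -> "EdgeTable":
        """Build from possibly unordered / duplicated rows.

        Duplicate (u,v)/(v,u) rows collapse by channel-wise maximum.
        """
        merged: dict[tuple[str, str], np.ndarray] = {}
        for a, b, ch in rows:
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            key = (a, b) if a < b else (b, a)
            vec = np.asarray(ch, dtype=float)
            if key in merged:
                merged[key] = np.maximum(merged[key], vec)
            else:
                merged[key] = vec
        keys = sorted(merged)
        ch = (
            np.array([merged[k] for k in keys], dtype=float)
            if keys
            else np.empty((0, N_CHANNELS))
        )
        return EdgeTable(
            u=tuple(k[0] for k in keys), v=tuple(k[1] for k in keys), channels=ch
        )

    def node_ids(self) -> set[str]:
        return set(self.u) | set(self.v)


def read_edge_table(path) -> EdgeTable:
    """Read a 7-column TSV (u, v, 5 channels) into a canonical EdgeTable."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["u", "v", *CHANNEL_NAMES]
    if list(df.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(df.columns)}")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        ch = np.asarray(row[2:], dtype=object)
        try:
            ch = ch.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: non-numeric channel score") from exc
        if not np.all(np.isfinite(ch)):
            raise ValidationError(f"row {i}: non-finite channel score")
        if np.any(ch < 0):
            raise ValidationError(f"row {i}: negative channel score")
        if row.u == row.v:
            raise ValidationError(f"row {i}: self-loop on node {row.u!r}")
        rows.append((str(row.u), str(row.v), ch))
    return EdgeTable.from_rows(rows)


def write_edge_table(table: EdgeTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["u", "v", *CHANNEL_NAMES]) + "\n")
        for a, b, ch in zip(table.u, table.v, table.channels):
            vals = "\t".join(FLOAT_FMT % x for x in ch)
            fh.write(f"{a}\t{b}\t{vals}\n")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-node feature vectors; rows follow ``node_ids`` order."""

    node_ids: tuple[str, ...]
    values: np.ndarray  # (n, D)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("feature values must be a 2-D matrix")
        if vals.shape[0] != len(self.node_ids):
            raise ValidationError("row count does not match node_ids")
        if vals.shape[0] and vals.shape[1] < 1:
            raise ValidationError("feature width must be >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite feature value")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def row(self, node_id: str) -> np.ndarray:
        return self.values[self.node_ids.index(node_id)]

    def sorted_by_id(self) -> "FeatureMatrix":
        order = np.argsort(np.asarray(self.node_ids, dtype=object))
        return FeatureMatrix(
            node_ids=tuple(self.node_ids[i] for i in order), values=self.values[order]
        )


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "node_id":
        raise ParseError(f"first column must be 'node_id', got {df.columns[0]!r}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return FeatureMatrix(node_ids=tuple(df["node_id"].astype(str)), values=values)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    width = matrix.values.shape[1] if matrix.values.size else matrix.dim
    cols = [f"f{i}" for i in range(width)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["node_id", *cols]) + "\n")
        for nid, row in zip(matrix.node_ids, matrix.values):
            fh.write(nid + "\t" + "\t".join(FLOAT_FMT % x for x in row) + "\n")


@dataclass(frozen=True)
class LevelGraph:
    """One level of the clustering hierarchy.

    Level 0 carries 5-channel edge scores; levels >= 1 carry a scalar
    similarity weight per edge plus a second ("peak") feature block.
    ``members`` maps each node to the set of level-0 gene ids it represents.
    """

    level: int
    node_ids: tuple[str, ...]
    node_features: np.ndarray  # (n, D)
    edges: np.ndarray  # (n_e, 2) int indices into node_ids, u_idx < v_idx
    edge_attr: np.ndarray  # (n_e, 5) at level 0 else (n_e, 1)
    peak_features: Optional[np.ndarray] = None
    members: Optional[Mapping[str, frozenset]] = None

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValidationError("level must be >= 0")
        feats = np.asarray(self.node_features, dtype=float)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        attr = np.asarray(self.edge_attr, dtype=float)
        if edges.shape[0] == 0:
            attr = np.zeros((0, N_CHANNELS if self.level == 0 else 1))
        else:
            attr = attr.reshape(edges.shape[0], -1)
        n = len(self.node_ids)
        if feats.shape[0] != n:
            raise ValidationError("feature row count != node count")
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValidationError("edge endpoint index out of range")
        if np.any(edges[:, 0] >= edges[:, 1]):
            raise ValidationError("edges must satisfy u_idx < v_idx")
        want = N_CHANNELS if self.level == 0 else 1
        if attr.shape[1] != want:
            raise ValidationError(
                f"level-{self.level} edges need {want} attr column(s); got {attr.shape[1]}"
            )
        if self.peak_features is not None:
            pk = np.asarray(self.peak_features, dtype=float)
            if pk.shape != feats.shape:
                raise ValidationError("peak_features shape must match node_features")
            pk.setflags(write=False)
            object.__setattr__(self, "peak_features", pk)
        members = self.members
        if members is None:
            members = {nid: frozenset([nid]) for nid in self.node_ids}
        for f in (feats, edges, attr):
            f.setflags(write=False)
        object.__setattr__(self, "node_features", feats)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "edge_attr", attr)
        object.__setattr__(self, "members", dict(members))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-node list of (neighbor index, edge index)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for e, (a, b) in enumerate(self.edges):
            adj[a].append((b, e))
            adj[b].append((a, e))
        return adj

    def encoder_input(self) -> np.ndarray:
        """Feature block consumed by the encoder: mean features at level 0,
        mean ⊕ peak concatenation above."""
        if self.level == 0 or self.peak_features is None:
            return self.node_features
        return np.hstack([self.node_features, self.peak_features])


def build_affinity_graph(
    edges: EdgeTable, features: FeatureMatrix, normalize: bool = False
) -> LevelGraph:
    """Assemble the level-0 affinity graph from a canonical edge table and a
    feature matrix.

    Every edge endpoint must appear in ``features.node_ids``.  Nodes are
    ordered by sorted id.  With ``normalize=True`` each channel is divided by
    its maximum (channels are otherwise taken as-is).
    """
    missing = sorted(edges.node_ids() - set(features.node_ids))
    if missing:
        raise ValidationError(f"edge endpoints missing from features: {missing}")
    fm = features.sorted_by_id()
    index = {nid: i for i, nid in enumerate(fm.node_ids)}
    idx = np.array(
        [[index[a], index[b]] for a, b in zip(edges.u, edges.v)], dtype=np.int64
    ).reshape(-1, 2)
    attr = np.array(edges.channels, dtype=float).reshape(-1, N_CHANNELS)
    if normalize and attr.size:
        scale = attr.max(axis=0)
        scale[scale == 0] = 1.0
        attr = attr / scale
    # canonicalize on index order (ids are sorted, so index order == id order)
    swap = idx[:, 0] > idx[:, 1]
    idx[swap] = idx[swap][:, ::-1]
    return LevelGraph(
        level=0,
        node_ids=fm.node_ids,
        node_features=fm.values,
        edges=idx,
        edge_attr=attr,
    )


def connected_components(
    graph: LevelGraph, edge_subset: Optional[Iterable[int]] = None
) -> dict[str, str]:
    """Partition nodes into connected components.

    ``edge_subset`` is an optional iterable of edge indices restricting the
    edge set.  Returns node id -> component id, where the component id is the
    smallest member node id.
    """
    n = graph.n_nodes
    if edge_subset is None:
        edges = graph.edges
    else:
        sub = sorted(set(edge_subset))
        if sub and (sub[0] < 0 or sub[-1] >= graph.n_edges):
            raise ValidationError("edge_subset index out of range")
        edges = graph.edges[sub] if sub else np.empty((0, 2), dtype=np.int64)
    if n == 0:
        return {}
    data = np.ones(edges.shape[0])
    adj = coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
    _, labels = _cc(adj, directed=False)
    comp_min: dict[int, str] = {}
    for i, lab in enumerate(labels):
        nid = graph.node_ids[i]
        if lab not in comp_min or nid < comp_min[lab]:
            comp_min[lab] = nid
    return {graph.node_ids[i]: comp_min[labels[i]] for i in range(n)}


def partition_from_components(assignment: Mapping[str, str]) -> dict[str, set[str]]:
    """Invert a node->component mapping into component -> member set."""
    out: dict[str, set[str]] = {}
    for node, comp in assignment.items():
        out.setdefault(comp, set()).add(node)
    return out
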