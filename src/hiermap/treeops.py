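"""Hierarchy data structure, ontology-format I/O, significance-guided pruning
and Cytoscape export.

The interchange format is a 3-column TSV (parent, child, relation) where
relation is "gene" when the child is a leaf gene and "system" otherwise.
Levels are canonical depths: genes are level 0 and each system's level is
1 + max(child level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

FLOAT_FMT = "%.12g"


class HierarchyError(ValueError):
    pass


@dataclass
class Hierarchy:
    """Tree of systems over gene leaves.

    ``children`` maps each system id to an ordered list of child ids (system
    or gene).  Each non-root has exactly one parent; every system covers at
    least 2 genes.
    """

    genes: tuple[str, ...]
    children: dict[str, list[str]]
    _gene_sets: dict[str, frozenset] = field(default_factory=dict, repr=False)
    _levels: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.children = {s: list(c) for s, c in self.children.items()}
        self.validate()

    # -- structural queries -------------------------------------------------
    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(self.children)

    def parent_map(self) -> dict[str, str]:
        parents: dict[str, str] = {}
        for sys_id, kids in self.children.items():
            for kid in kids:
                if kid in parents:
                    raise HierarchyError(
                        f"node {kid!r} has multiple parents ({parents[kid]!r}, {sys_id!r})"
                    )
                parents[kid] = sys_id
        return parents

    def roots(self) -> list[str]:
        parents = self.parent_map()
        return [s for s in self.children if s not in parents]

    def gene_set(self, sys_id: str) -> frozenset:
        if sys_id not in self._gene_sets:
            gene_pool = set(self.genes)
            out: set = set()
            stack = [sys_id]
            while stack:
                node = stack.pop()
                for kid in self.children.get(node, []):
                    if kid in self.children:
                        stack.append(kid)
                    elif kid in gene_pool:
                        out.add(kid)
                    else:
                        raise HierarchyError(f"unknown child {kid!r} of {node!r}")
            self._gene_sets[sys_id] = frozenset(out)
        return self._gene_sets[sys_id]

    def level(self, node_id: str) -> int:
        if node_id not in self.children:
            return 0
        if node_id not in self._levels:
            self._levels[node_id] = 1 + max(
                self.level(kid) for kid in self.children[node_id]
            )
        return self._levels[node_id]

    def max_level(self) -> int:
        return max((self.level(s) for s in self.children), default=0)

    def flatten_at_level(self, level: int) -> dict[str, str]:
        """Gene -> lowest ancestor system with level >= ``level`` (or itself)."""
        parents = self.parent_map()
        out: dict[str, str] = {}
        for g in self.genes:
            node = g
            assigned = g
            while node in parents:
                node = parents[node]
                if self.level(node) >= level:
                    assigned = node
                    break
            out[g] = assigned
        return out

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        gene_pool = set(self.genes)
        if len(gene_pool) != len(self.genes):
            raise HierarchyError("duplicate gene ids")
        overlap = gene_pool & set(self.children)
        if overlap:
            raise HierarchyError(f"ids used as both gene and system: {sorted(overlap)}")
        parents = self.parent_map()  # raises on multi-parent
        # acyclicity: walk up from every system; a cycle revisits a node
        for start in self.children:
            seen = {start}
            node = start
            while node in parents:
                node = parents[node]
                if node in seen:
                    raise HierarchyError(f"cycle through {node!r}")
                seen.add(node)
        self._gene_sets.clear()
        self._levels.clear()
        for sys_id in self.children:
            if not self.children[sys_id]:
                raise HierarchyError(f"system {sys_id!r} has no children")
            if len(self.gene_set(sys_id)) < 2:
                raise HierarchyError(
                    f"system {sys_id!r} covers {len(self.gene_set(sys_id))} gene(s); >= 2 required"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hierarchy):
            return NotImplemented
        return set(self.genes) == set(other.genes) and {
            s: set(c) for s, c in self.children.items()
        } == {s: set(c) for s, c in other.children.items()}


def read_ontology(path) -> Hierarchy:
    """Read a 3-column (parent, child, relation) TSV into a Hierarchy."""
    children: dict[str, list[str]] = {}
    genes: list[str] = []
    seen_genes: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#orphan\t"):
                gene = line.split("\t", 1)[1]
                if gene and gene not in seen_genes:
                    seen_genes.add(gene)
                    genes.append(gene)
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise HierarchyError(f"line {lineno}: expected 3 tab-separated columns")
            parent, child, relation = parts
            if relation not in ("system", "gene"):
                raise HierarchyError(
                    f"line {lineno}: unknown relation {relation!r} on edge {parent!r}->{child!r}"
                )
            children.setdefault(parent, [])
            if child in children.get(parent, []):
                raise HierarchyError(f"line {lineno}: duplicate edge {parent!r}->{child!r}")
            children[parent].append(child)
            if relation == "gene":
                if child not in seen_genes:
                    seen_genes.add(child)
                    genes.append(child)
            else:
                children.setdefault(child, [])
    try:
        return Hierarchy(genes=tuple(genes), children=children)
    except HierarchyError as exc:
        raise HierarchyError(f"invalid ontology file {path}: {exc}") from exc


def write_ontology(hierarchy: Hierarchy, path) -> None:
    """Write the 3-column edge list.  Genes attached to no system are kept
    as ``#orphan`` annotation lines (ignored as comments by other tools)."""
    attached: set = set()
    for kids in hierarchy.children.values():
        attached.update(kids)
    with open(path, "w", encoding="utf-8") as fh:
        for sys_id in sorted(hierarchy.children):
            for kid in sorted(hierarchy.children[sys_id]):
                rel = "system" if kid in hierarchy.children else "gene"
                fh.write(f"{sys_id}\t{kid}\t{rel}\n")
        for gene in sorted(set(hierarchy.genes) - attached):
            fh.write(f"#orphan\t{gene}\n")


def prune_hierarchy(hierarchy: Hierarchy, significant: Iterable[str]) -> Hierarchy:
    """Remove insignificant internal systems, bottom-up.

    Each non-significant, non-root system is dropped and its children
    re-attach to its parent.  Roots are retained regardless of significance
    so the tree stays connected; gene leaves are never removed.
    """
    significant = set(significant)
    unknown = significant - set(hierarchy.children)
    if unknown:
        raise HierarchyError(f"significant ids not in hierarchy: {sorted(unknown)}")
    children = {s: list(c) for s, c in hierarchy.children.items()}
    parents = hierarchy.parent_map()
    order = sorted(children, key=lambda s: (hierarchy.level(s), s))  # bottom-up
    for sys_id in order:
        if sys_id in significant or sys_id not in parents:
            continue
        parent = parents[sys_id]
        kids = children.pop(sys_id)
        plist = children[parent]
        i = plist.index(sys_id)
        children[parent] = plist[:i] + kids + plist[i + 1 :]
        for kid in kids:
            parents[kid] = parent
        del parents[sys_id]
    return Hierarchy(genes=hierarchy.genes, children=children)


def export_cytoscape(
    hierarchy: Hierarchy,
    node_attributes: Mapping[str, Mapping[str, object]],
    sif_path,
    attr_path,
) -> list[str]:
    """Write a SIF file (one ``parent contains child`` line per edge) and a
    node-attribute TSV.  Attributes for unknown nodes are skipped with a
    warning message returned to the caller."""
    warnings: list[str] = []
    known = set(hierarchy.genes) | set(hierarchy.children)
    with open(sif_path, "w", encoding="utf-8") as fh:
        for sys_id in sorted(hierarchy.children):
            for kid in sorted(hierarchy.children[sys_id]):
                fh.write(f"{sys_id}\tcontains\t{kid}\n")
    keys: list[str] = []
    for node, attrs in node_attributes.items():
        for k in attrs:
            if k not in keys:
                keys.append(k)
    with open(attr_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["node_id", *keys]) + "\n")
        for node in sorted(node_attributes):
            if node not in known:
                warnings.append(f"attribute row for unknown node {node!r} skipped")
                continue
            attrs = node_attributes[node]
            cells = []
            for k in keys:
                v = attrs.get(k, "")
                if isinstance(v, float):
                    cells.append(FLOAT_FMT % v)
                else:
                    cells.append(str(v))
            fh.write("\t".join([node, *cells]) + "\n")
    return warnings
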