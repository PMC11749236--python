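"""Clustering agreement metrics: pairwise F, BCubed F and NMI.

All three operate on two partitions over the same element set and live in
[0, 1].  Formulas are computed from the joint contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np


Partition = Mapping[Hashable, Hashable]


@dataclass(frozen=True)
class MetricsReport:
    fp: float
    fb: float
    nmi: float
    n_elements: int
    n_pred_clusters: int
    n_true_clusters: int

    def as_dict(self) -> dict:
        return {
            "fp": self.fp,
            "fb": self.fb,
            "nmi": self.nmi,
            "n_elements": self.n_elements,
            "n_pred_clusters": self.n_pred_clusters,
            "n_true_clusters": self.n_true_clusters,
        }


def _check_elements(pred: Partition, true: Partition) -> None:
    if set(pred) != set(true):
        diff = sorted(map(repr, set(pred) ^ set(true)))
        raise ValueError(f"element sets differ; symmetric difference: {diff}")
    if not pred:
        raise ValueError("empty partitions")


def _contingency(pred: Partition, true: Partition) -> np.ndarray:
    elements = list(pred)
    pred_ids = {c: i for i, c in enumerate(dict.fromkeys(pred[e] for e in elements))}
    true_ids = {c: i for i, c in enumerate(dict.fromkeys(true[e] for e in elements))}
    table = np.zeros((len(pred_ids), len(true_ids)), dtype=float)
    for e in elements:
        table[pred_ids[pred[e]], true_ids[true[e]]] += 1
    return table


def pairwise_f(pred: Partition, true: Partition) -> tuple[float, float, float]:
    """Precision/recall/F over same-cluster element pairs.

    If both partitions have no same-cluster pair (all singletons), the score
    is 1 by convention.
    """
    _check_elements(pred, true)
    table = _contingency(pred, true)

    def pairs(counts: np.ndarray) -> float:
        return float(np.sum(counts * (counts - 1) / 2))

    tp = pairs(table)  # pairs together in both
    pred_pairs = pairs(table.sum(axis=1))
    true_pairs = pairs(table.sum(axis=0))
    if pred_pairs == 0 and true_pairs == 0:
        return 1.0, 1.0, 1.0
    precision = tp / pred_pairs if pred_pairs > 0 else 1.0
    recall = tp / true_pairs if true_pairs > 0 else 1.0
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def bcubed_f(pred: Partition, true: Partition) -> tuple[float, float, float]:
    """Element-averaged BCubed precision/recall and their harmonic mean."""
    _check_elements(pred, true)
    table = _contingency(pred, true)
    n = table.sum()
    pred_sizes = table.sum(axis=1, keepdims=True)
    true_sizes = table.sum(axis=0, keepdims=True)
    # each cell contributes its count of elements, each with precision
    # cell/pred_size and recall cell/true_size
    precision = float(np.sum(table * table / pred_sizes) / n)
    recall = float(np.sum(table * table / true_sizes) / n)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def nmi(pred: Partition, true: Partition) -> float:
    """Normalized mutual information, 2·I/(H(U)+H(V)) with natural logs.

    Identical partitions score 1 (even when degenerate); otherwise a zero
    entropy sum scores 0.
    """
    _check_elements(pred, true)
    elements = list(pred)
    # identity up to relabeling
    mapping: dict = {}
    rmapping: dict = {}
    identical = True
    for e in elements:
        a, b = pred[e], true[e]
        if mapping.setdefault(a, b) != b or rmapping.setdefault(b, a) != a:
            identical = False
            break
    if identical:
        return 1.0
    table = _contingency(pred, true)
    n = table.sum()
    pu = table.sum(axis=1) / n
    pv = table.sum(axis=0) / n
    hu = float(-np.sum(pu * np.log(pu, where=pu > 0, out=np.zeros_like(pu))))
    hv = float(-np.sum(pv * np.log(pv, where=pv > 0, out=np.zeros_like(pv))))
    if hu + hv == 0:
        return 0.0
    pj = table / n
    outer = np.outer(pu, pv)
    mask = pj > 0
    mi = float(np.sum(pj[mask] * np.log(pj[mask] / outer[mask])))
    val = 2.0 * mi / (hu + hv)
    return min(max(val, 0.0), 1.0)


def metrics_report(pred: Partition, true: Partition) -> MetricsReport:
    _, _, fp = pairwise_f(pred, true)
    _, _, fb = bcubed_f(pred, true)
    return MetricsReport(
        fp=fp,
        fb=fb,
        nmi=nmi(pred, true),
        n_elements=len(pred),
        n_pred_clusters=len(set(pred.values())),
        n_true_clusters=len(set(true.values())),
    )


def evaluate_hierarchy_level(
    hierarchy,
    labels,
    level: int,
    element_subset: Optional[Sequence[Hashable]] = None,
) -> MetricsReport:
    """Compare a hierarchy, flattened at ``level``, against a label partition.

    Each gene maps to its lowest ancestor system of level >= ``level`` (or to
    itself when it has none); metrics run over ``element_subset`` intersected
    with the labeled genes.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    available = hierarchy.max_level()
    if level > available:
        raise ValueError(f"hierarchy has max level {available}; requested {level}")
    flat = hierarchy.flatten_at_level(level)
    genes = set(labels.assignments)
    if element_subset is not None:
        genes &= set(element_subset)
    genes &= set(hierarchy.genes)
    if not genes:
        raise ValueError("no evaluable genes (empty subset/label intersection)")
    pred = {g: flat[g] for g in genes}
    true = {g: labels.assignments[g] for g in genes}
    return metrics_report(pred, true)
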