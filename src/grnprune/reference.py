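"""Distance-thresholded reference GRN construction and network statistics.

A TF is assigned to the regulation of a gene when one of its ChIP-Seq peaks
lies within a chosen distance of the gene's TSS.  The window is symmetric
(upstream and downstream) and the distance from a peak to a TSS is the
interval-to-point minimum: zero if the TSS falls inside the peak, otherwise
the gap to the nearest covered base.  With this definition the edge sets are
nested across increasing thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Gene, NetworkSummary, Peak, RegulatoryNetwork


def assign_tfs(
    peaks: Iterable[Peak],
    genes: Sequence[Gene],
    threshold: int,
    anchor: str = "interval",
) -> RegulatoryNetwork:
    """Build the reference network: edge (tf, g) iff some peak of ``tf`` is
    within ``threshold`` nucleotides of g's TSS.

    ``anchor`` selects the peak reference point: ``"interval"`` (default)
    measures from the nearest peak boundary with distance 0 inside the peak;
    ``"midpoint"`` measures from the peak midpoint.  Multiple qualifying
    peaks of one TF collapse to a single unweighted edge.  Peaks on
    chromosomes absent from the annotation are skipped with a warning.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene catalog")
    if anchor not in ("interval", "midpoint"):
        raise ValueError(f"anchor must be 'interval' or 'midpoint', got {anchor!r}")

    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, group in _group_genes(genes).items():
        group.sort(key=lambda g: g.tss)
        tss = np.array([g.tss for g in group], dtype=np.int64)
        ids = [g.gene_id for g in group]
        by_chrom[chrom] = (tss, ids)

    edges: set[tuple[str, str]] = set()
    missing: set[str] = set()
    for peak in peaks:
        iv = peak.interval
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            missing.add(iv.chrom)
            continue
        tss, ids = entry
        if anchor == "interval":
            lo = iv.start - threshold
            hi = (iv.end - 1) + threshold
        else:
            mid = (iv.start + iv.end - 1) / 2.0
            lo = mid - threshold
            hi = mid + threshold
        i = int(np.searchsorted(tss, lo, side="left"))
        j = int(np.searchsorted(tss, hi, side="right"))
        for k in range(i, j):
            edges.add((peak.tf_id, ids[k]))
    if missing:
        warnings.warn(
            f"skipped peaks on chromosomes absent from annotation: {sorted(missing)}",
            stacklevel=2,
        )
    return RegulatoryNetwork(edges, label=f"reference_{threshold}")


def _group_genes(genes: Sequence[Gene]) -> dict[str, list[Gene]]:
    out: dict[str, list[Gene]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    return out


def summarize(net: RegulatoryNetwork) -> NetworkSummary:
    """Node count, edge count and average in/outdegree.

    ``avg_indegree`` divides edges by the number of distinct targets and
    ``avg_outdegree`` by the number of TFs with at least one out-edge, so
    ``avg_outdegree * n_tfs_with_out_edges == n_edges`` exactly.
    """
    n_edges = len(net.edges)
    if n_edges == 0:
        return NetworkSummary(0, 0, 0.0, 0.0)
    n_targets = len(net.target_ids)
    n_tfs = len(net.tf_ids)
    return NetworkSummary(
        n_genes=len(net.nodes),
        n_edges=n_edges,
        avg_indegree=n_edges / n_targets,
        avg_outdegree=n_edges / n_tfs,
    )


@dataclass
class EdgeComparison:
    """Per-edge membership over several networks plus Venn-style region counts."""

    labels: tuple[str, ...]
    table: pd.DataFrame  # index: (tf, target) tuples; one bool column per label

    def region_counts(self) -> dict[tuple[bool, ...], int]:
        """Count of union edges per membership pattern (True = present)."""
        counts: dict[tuple[bool, ...], int] = {}
        for row in self.table.itertuples(index=False):
            key = tuple(bool(v) for v in row)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def intersection_size(self) -> int:
        return int(self.table.all(axis=1).sum())

    def union_size(self) -> int:
        return len(self.table)


def compare_edge_sets(nets: Sequence[RegulatoryNetwork]) -> EdgeComparison:
    """Edge-level comparison of two or three networks, edges identified by
    their (source, target) id pair."""
    if not 2 <= len(nets) <= 3:
        raise ValueError(f"expected 2-3 networks, got {len(nets)}")
    labels = []
    for i, net in enumerate(nets):
        lab = net.label or f"net{i}"
        while lab in labels:
            lab = f"{lab}_{i}"
        labels.append(lab)
    union = sorted(set().union(*(net.edges for net in nets)))
    data = {
        lab: [e in net.edges for e in union] for lab, net in zip(labels, nets)
    }
    table = pd.DataFrame(data, index=pd.Index(union, name="edge", tupleize_cols=False))
    return EdgeComparison(tuple(labels), table)
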