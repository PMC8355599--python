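"""Core domain types shared across the package.

Coordinate convention: everything in memory is 0-based half-open, the BED
convention.  GTF/GFF input (1-based inclusive) is converted on read and back
on write, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

Edge = tuple[str, str]  # (tf_id, target_id), directed


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to(self, pos: int) -> int:
        """Minimum distance from this interval to a point.

        Zero if the point lies inside ``[start, end)``; otherwise the gap to
        the nearest covered base (``end - 1`` is the last covered base).
        """
        if self.start <= pos < self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - (self.end - 1)))


@dataclass(frozen=True)
class Peak:
    """A ChIP-Seq binding interval attributed to one TF."""

    interval: GenomicInterval
    tf_id: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.tf_id:
            raise ValueError("tf_id must be non-empty")
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")


@dataclass(frozen=True)
class Gene:
    """An annotated gene reduced to its strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


class RegulatoryNetwork:
    """A directed TF -> target edge set.

    Nodes are implied by the edges: a node "is in" the network iff it has at
    least one incident edge, which matches how the networks here are counted
    (a gene that loses all regulators disappears).  TF -> TF edges are
    allowed; duplicates collapse.
    """

    __slots__ = ("edges", "label")

    def __init__(self, edges: Iterable[Edge], label: str = "") -> None:
        self.edges: frozenset[Edge] = frozenset((str(a), str(b)) for a, b in edges)
        self.label = label

    @property
    def tf_ids(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.edges)

    @property
    def target_ids(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    @property
    def nodes(self) -> frozenset[str]:
        return self.tf_ids | self.target_ids

    def regulators_of(self, target_id: str) -> frozenset[str]:
        return frozenset(tf for tf, t in self.edges if t == target_id)

    def targets_of(self, tf_id: str) -> frozenset[str]:
        return frozenset(t for tf, t in self.edges if tf == tf_id)

    def regulator_map(self) -> dict[str, set[str]]:
        """target -> set of regulators, one pass over the edge set."""
        out: dict[str, set[str]] = {}
        for tf, t in self.edges:
            out.setdefault(t, set()).add(tf)
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return (
            f"<RegulatoryNetwork{lab}: {len(self.edges)} edges, "
            f"{len(self.tf_ids)} TFs, {len(self.target_ids)} targets>"
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Node/edge counts and degree averages of a regulatory network."""

    n_genes: int
    n_edges: int
    avg_indegree: float
    avg_outdegree: float


class InteractionNetwork:
    """An undirected TF-TF interaction network (PPI, STRING, co-expression).

    Unlike :class:`RegulatoryNetwork`, the node set is declared explicitly:
    connectance needs to know which TFs the resource covers, and resources
    like STRING list scored nodes that may end up with no retained edge.
    """

    __slots__ = ("nodes", "edges", "source_label")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        nodes: Optional[Iterable[str]] = None,
        source_label: str = "",
    ) -> None:
        canon = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-interaction {a!r}-{b!r} not allowed")
            canon.add((a, b) if a <= b else (b, a))
        self.edges: frozenset[tuple[str, str]] = frozenset(canon)
        implied = {n for e in canon for n in e}
        self.nodes: frozenset[str] = (
            frozenset(str(n) for n in nodes) | implied if nodes is not None else frozenset(implied)
        )
        self.source_label = source_label

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a <= b else (b, a)) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:
        lab = f" {self.source_label!r}" if self.source_label else ""
        return f"<InteractionNetwork{lab}: {len(self.nodes)} nodes, {len(self.edges)} edges>"


class ExpressionMatrix:
    """A genes x samples matrix of non-negative expression values.

    Thin validated wrapper around a pandas DataFrame (rows = genes,
    columns = samples), the container everything downstream consumes.
    """

    __slots__ = ("data",)

    def __init__(self, data: pd.DataFrame) -> None:
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.data = data

    @classmethod
    def from_arrays(
        cls, gene_ids: Iterable[str], sample_ids: Iterable[str], values: np.ndarray
    ) -> "ExpressionMatrix":
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids)))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float, copy=False)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index

    def row(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def submatrix(self, gene_ids: Iterable[str]) -> np.ndarray:
        return self.data.loc[list(gene_ids)].to_numpy(dtype=float)

    def zscores(self) -> pd.DataFrame:
        """Per-gene standardized values; zero-variance genes become NaN rows."""
        v = self.values
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        # constant rows are detected exactly (ptp == 0); their std can come
        # out as a rounding-noise positive under float summation
        constant = np.ptp(v, axis=1, keepdims=True) == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(~constant & (sd > 0), (v - mu) / sd, np.nan)
        return pd.DataFrame(z, index=self.data.index, columns=self.data.columns)


@dataclass
class SyntheticTruth:
    """Ground truth bundled with a synthetic benchmark instance."""

    true_net: RegulatoryNetwork
    weights: Mapping[Edge, float]
    noise_sd: float
    decoy_candidates: Mapping[str, frozenset[str]]
    tf_ids: tuple[str, ...] = field(default_factory=tuple)
    target_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for gene, decoys in self.decoy_candidates.items():
            true_regs = self.true_net.regulators_of(gene)
            if true_regs & decoys:
                raise ValueError(f"gene {gene}: decoys overlap true regulators")
        for edge, w in self.weights.items():
            if edge not in self.true_net.edges:
                raise ValueError(f"weight on non-true edge {edge}")
            if w == 0:
                raise ValueError(f"zero weight on true edge {edge}")
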