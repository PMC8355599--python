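"""Per-gene pruning of candidate regulators with tree-ensemble importances.

The second step of the two-step protocol: for each target gene, a random
forest of regression trees is trained to predict the gene's (standardized)
expression from the expression of only those TFs the distance step assigned
to it.  A candidate's importance is the mean over trees of the total
sample-weighted variance reduction at nodes splitting on it.  Candidates
scoring below a fixed fraction (default 10%) of the gene's top importance
are removed; the top candidate therefore always survives.

Each tree is grown on a bootstrap resample, choosing the best
variance-reducing split among ``k_split`` randomly drawn candidates per
node.  The ensemble is delegated to scikit-learn's ``RandomForestRegressor``
with per-tree unnormalized impurity importances, which computes exactly this
quantity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from math import ceil, sqrt
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import ZeroVarianceTarget
from .model import ExpressionMatrix, RegulatoryNetwork

MIN_SAMPLES = 10


@dataclass(frozen=True)
class PruningParams:
    """Forest and threshold settings for the pruning step.

    n_trees : trees per gene's forest; 1000 for production runs, 100 is
        adequate for simulation-scale work.
    k_split : candidates considered per split; None means ceil(sqrt(p)) for
        p candidates, the usual random-forest default.
    min_samples_split : minimum node size eligible for splitting.
    relevance_fraction : retain a TF iff its importance is at least this
        fraction of the gene's maximum importance (strictly-below is cut).
    seed : global seed; per-gene seeds are derived from it and the gene id.
    """

    n_trees: int = 1000
    k_split: Optional[int] = None
    min_samples_split: int = 2
    relevance_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")
        if self.k_split is not None and self.k_split <= 0:
            raise ValueError("k_split must be positive")
        if self.min_samples_split <= 0:
            raise ValueError("min_samples_split must be positive")
        if not 0 < self.relevance_fraction <= 1:
            raise ValueError("relevance_fraction must be in (0, 1]")


@dataclass
class ImportanceTable:
    """Importance scores of one gene's candidate regulators."""

    target_id: str
    scores: Mapping[str, float]
    n_samples_used: int
    seed: int

    def ranked(self) -> list[tuple[str, float]]:
        """Candidates sorted by decreasing importance (id as tie-break)."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


def gene_seed(global_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed, independent of iteration order."""
    digest = hashlib.blake2b(
        f"{global_seed}:{gene_id}".encode("utf-8"), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def forest_importance(
    target_expr: np.ndarray,
    candidate_expr: np.ndarray,
    candidate_ids: Sequence[str],
    params: PruningParams,
    target_id: str = "",
    seed: Optional[int] = None,
) -> ImportanceTable:
    """Score each candidate TF by its variance-reduction importance.

    ``candidate_expr`` is candidates x samples.  The target is standardized
    to zero mean, unit variance before fitting so importances are comparable
    across genes; candidate rows are used raw (tree splits are invariant to
    monotone predictor scaling).
    """
    y = np.asarray(target_expr, dtype=float)
    X = np.asarray(candidate_expr, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(candidate_ids):
        raise ValueError("candidate_expr must be (candidates x samples)")
    if X.shape[1] != y.shape[0]:
        raise ValueError("candidate and target sample counts differ")
    if y.shape[0] < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {y.shape[0]}")
    if len(candidate_ids) == 0:
        raise ValueError("no candidates")
    if target_id and target_id in candidate_ids:
        raise ValueError(f"target {target_id!r} cannot be its own candidate")
    sd = y.std()
    if np.ptp(y) == 0 or sd == 0:  # exact constant check; std has rounding noise
        raise ZeroVarianceTarget(target_id or "<target>")
    y = (y - y.mean()) / sd

    p = len(candidate_ids)
    k = params.k_split if params.k_split is not None else ceil(sqrt(p))
    rf_seed = seed if seed is not None else params.seed
    forest = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=min(k, p),
        min_samples_split=params.min_samples_split,
        bootstrap=True,
        random_state=rf_seed,
        n_jobs=1,
    )
    forest.fit(X.T, y)
    # mean over trees of total weighted variance reduction per feature
    imp = np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in forest.estimators_],
        axis=0,
    )
    scores = {cid: float(v) for cid, v in zip(candidate_ids, imp)}
    return ImportanceTable(target_id, scores, n_samples_used=y.shape[0], seed=rf_seed)


def dynamic_threshold(table: ImportanceTable, fraction: float) -> frozenset[str]:
    """TFs whose importance is at least ``fraction`` of the gene's maximum.

    Removal applies to scores *strictly below* the cutoff, so a score exactly
    equal to ``fraction * max`` is kept and the top TF always survives.
    """
    if not table.scores:
        raise ValueError(f"empty importance table for {table.target_id!r}")
    cutoff = fraction * max(table.scores.values())
    return frozenset(tf for tf, s in table.scores.items() if s >= cutoff)


def prune_network(
    refnet: RegulatoryNetwork,
    expr: ExpressionMatrix,
    params: PruningParams,
    progress: bool = False,
) -> RegulatoryNetwork:
    """Prune a reference network gene by gene.

    For each target gene found in the expression matrix with nonzero
    variance, its candidate regulators are the reference regulators also in
    the matrix (never the gene itself); edges are retained per
    :func:`forest_importance` + :func:`dynamic_threshold`.  Targets missing
    from the matrix, with constant expression, or with no usable candidate
    are dropped entirely — this is what shrinks the node count.  Per-gene
    seeds derive from ``params.seed`` and the gene id, so results do not
    depend on iteration order.
    """
    reg_map = refnet.regulator_map()
    shared = set(reg_map) | refnet.tf_ids
    if not (shared & set(expr.gene_ids)):
        raise ValueError("reference network and expression matrix share no gene ids")

    kept: set[tuple[str, str]] = set()
    for target in sorted(reg_map):
        if target not in expr:
            continue
        candidates = sorted(c for c in reg_map[target] if c != target and c in expr)
        if not candidates:
            continue
        y = expr.row(target)
        if np.ptp(y) == 0:
            continue
        X = expr.submatrix(candidates)
        table = forest_importance(
            y, X, candidates, params, target_id=target,
            seed=gene_seed(params.seed, target),
        )
        retained = dynamic_threshold(table, params.relevance_fraction)
        kept.update((tf, target) for tf in retained)
        if progress:
            print(f"{target}: kept {len(retained)}/{len(candidates)}", flush=True)
    label = f"{refnet.label}|pruned" if refnet.label else "pruned"
    return RegulatoryNetwork(kept, label=label)


def with_seed(params: PruningParams, seed: int) -> PruningParams:
    return replace(params, seed=seed)
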