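"""Quality metrics for pruned networks.

Two complementary checks, both grounded in the biology of transcriptional
complexes (TFs that co-regulate a gene tend to physically or functionally
interact, and genes sharing regulators tend to be co-expressed):

* connectance — for each gene, how densely its assigned regulators are
  interconnected in an independent TF-TF interaction network, compared
  before vs after pruning;
* co-expression of co-regulated gene pairs — the mean Pearson correlation
  of target pairs sharing at least k regulators, before vs after, with a
  Welch two-sample t-test on the two correlation samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import nan
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .model import ExpressionMatrix, InteractionNetwork, RegulatoryNetwork


def connectance(regulators: Iterable[str], ppi: InteractionNetwork) -> Optional[float]:
    """Fraction of realized interactions among a gene's regulators.

    With n regulators there are n(n-1)/2 possible unordered pairs; the
    connectance rho is the fraction of those present as edges in ``ppi``.
    Regulators absent from the interaction network still count in the
    denominator (incomplete interaction coverage depresses rho rather than
    silently shrinking the set).  Undefined (None) for n < 2.
    """
    regs = sorted(set(regulators))
    n = len(regs)
    if n < 2:
        return None
    hits = sum(1 for a, b in combinations(regs, 2) if ppi.has_edge(a, b))
    return hits / (n * (n - 1) / 2)


@dataclass
class ConnectanceReport:
    """Per-gene connectance before/after pruning plus the better/worse/equal split."""

    per_gene: dict[str, tuple[Optional[float], Optional[float]]]
    better: float
    worse: float
    equal: float
    n_comparable: int
    n_undefined: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "rho_before": b, "rho_after": a}
            for g, (b, a) in sorted(self.per_gene.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "rho_before", "rho_after"])


def compare_connectance(
    before: RegulatoryNetwork,
    after: RegulatoryNetwork,
    ppi: InteractionNetwork,
) -> ConnectanceReport:
    """Count, over genes with defined connectance in both networks, the
    fraction whose regulator connectance rose / fell / stayed exact-equal
    after pruning.

    Both rhos are rationals with known denominators, so equality is exact.
    Genes with fewer than two regulators in either network are excluded from
    the fractions and reported in ``n_undefined``.
    """
    if not after.target_ids <= before.target_ids:
        raise ValueError("after-network targets must be a subset of before-network targets")
    before_map = before.regulator_map()
    after_map = after.regulator_map()
    per_gene: dict[str, tuple[Optional[float], Optional[float]]] = {}
    n_better = n_worse = n_equal = n_undef = 0
    for gene in sorted(after_map):
        rho_b = connectance(before_map[gene], ppi)
        rho_a = connectance(after_map[gene], ppi)
        per_gene[gene] = (rho_b, rho_a)
        if rho_b is None or rho_a is None:
            n_undef += 1
        elif rho_a > rho_b:
            n_better += 1
        elif rho_a < rho_b:
            n_worse += 1
        else:
            n_equal += 1
    n_cmp = n_better + n_worse + n_equal
    frac = (lambda k: k / n_cmp if n_cmp else 0.0)
    return ConnectanceReport(
        per_gene=per_gene,
        better=frac(n_better),
        worse=frac(n_worse),
        equal=frac(n_equal),
        n_comparable=n_cmp,
        n_undefined=n_undef,
    )


def correlation_network(
    expr: ExpressionMatrix,
    tf_ids: Iterable[str],
    threshold: float,
    absolute: bool = False,
) -> InteractionNetwork:
    """TF-TF co-expression network: edge iff Pearson r >= threshold.

    Positive-correlation convention by default; ``absolute=True`` compares
    |r| instead.  Node set = TFs with at least one retained edge, which is
    why the node count shrinks as the threshold rises.  TFs missing from
    the matrix or with zero variance are excluded with a warning.
    """
    if not -1 < threshold < 1:
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    wanted = sorted(set(tf_ids))
    present = [t for t in wanted if t in expr]
    if len(present) < len(wanted):
        warnings.warn(
            f"{len(wanted) - len(present)} TFs absent from expression matrix",
            stacklevel=2,
        )
    sub = expr.data.loc[present].to_numpy(dtype=float)
    spread = np.ptp(sub, axis=1)  # exact constant check
    if (spread == 0).any():
        dropped = [t for t, s in zip(present, spread) if s == 0]
        warnings.warn(f"excluding zero-variance TFs: {dropped[:5]}", stacklevel=2)
        present = [t for t, s in zip(present, spread) if s > 0]
        sub = expr.data.loc[present].to_numpy(dtype=float)
    edges = []
    if len(present) >= 2:
        r = np.corrcoef(sub)
        val = np.abs(r) if absolute else r
        iu, ju = np.triu_indices(len(present), k=1)
        for i, j in zip(iu, ju):
            if val[i, j] >= threshold:
                edges.append((present[i], present[j]))
    return InteractionNetwork(edges, source_label=f"corr_{threshold:g}")


def filter_scored_edges(
    edges: pd.DataFrame,
    score_field: str,
    min_score: float,
) -> InteractionNetwork:
    """Threshold a STRING-style scored edge table into an interaction network.

    ``edges`` must have protein1/protein2 pair columns (first two) and one
    numeric column per evidence channel; scores on a 0-1000 scale are
    rescaled to 0-1 before comparison.  Pairs with score >= min_score are
    kept.
    """
    score_cols = list(edges.columns[2:])
    if score_field not in edges.columns:
        raise ConfigurationError(
            f"unknown score field {score_field!r}; available: {score_cols}"
        )
    scores = pd.to_numeric(edges[score_field], errors="raise").astype(float)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    keep = edges.loc[scores >= min_score]
    pair_cols = list(edges.columns[:2])
    out = [
        (a, b)
        for a, b in zip(keep[pair_cols[0]], keep[pair_cols[1]])
        if a != b
    ]
    return InteractionNetwork(out, source_label=f"{score_field}>={min_score:g}")


def welch_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test: statistic for a - b and
    two-sided p-value."""
    t, p = stats.ttest_ind(sample_a, sample_b, equal_var=False)
    return float(t), float(p)


@dataclass
class CoexprRow:
    k: int
    n_pairs_before: int
    mean_r_before: float
    n_pairs_after: int
    mean_r_after: float
    t_statistic: float
    p_value: float


@dataclass
class CoexprReport:
    """Co-expression of co-regulated target pairs, before vs after pruning.

    The paired-sample significance threshold used in reporting is
    p <= 5e-4 (two-sided), kept here for reference; raw p-values are
    reported without multiple-testing correction.
    """

    per_k: dict[int, CoexprRow]
    significance_level: float = 5e-4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.per_k.values()]).set_index("k")


def _shared_regulator_pairs(net: RegulatoryNetwork) -> dict[tuple[str, str], int]:
    """Unordered target pairs -> number of shared regulators."""
    counts: dict[tuple[str, str], int] = {}
    by_tf: dict[str, list[str]] = {}
    for tf, t in net.edges:
        by_tf.setdefault(tf, []).append(t)
    for targets in by_tf.values():
        for a, b in combinations(sorted(targets), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def coexpression_comparison(
    before: RegulatoryNetwork,
    after: RegulatoryNetwork,
    expr: ExpressionMatrix,
    k_max: int,
) -> CoexprReport:
    """For each k in 2..k_max compare Pearson correlations of target pairs
    sharing at least k regulators, after vs before pruning.

    Pair sets are cumulative ("at least k").  The t statistic is Welch's,
    oriented after-minus-before, so positive t means the pruned network's
    co-regulated pairs are more co-expressed.  A k with fewer than two
    usable pairs on either side is reported with NaN statistics.  Pairs
    involving genes absent from the matrix or with zero variance are
    dropped (their correlation is not computable).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    z = expr.zscores()
    zv = z.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(z.index)}
    n_samples = zv.shape[1]

    def pair_correlations(counts: dict[tuple[str, str], int], k: int) -> np.ndarray:
        rs = []
        for (a, b), c in counts.items():
            if c < k or a not in index or b not in index:
                continue
            za, zb = zv[index[a]], zv[index[b]]
            if np.isnan(za).any() or np.isnan(zb).any():
                continue  # zero-variance gene
            rs.append(float(za @ zb) / n_samples)
        return np.asarray(rs)

    counts_before = _shared_regulator_pairs(before)
    counts_after = _shared_regulator_pairs(after)
    per_k: dict[int, CoexprRow] = {}
    for k in range(2, k_max + 1):
        r_b = pair_correlations(counts_before, k)
        r_a = pair_correlations(counts_after, k)
        if len(r_b) < 2 or len(r_a) < 2:
            t = p = nan
        else:
            t, p = welch_t(r_a, r_b)
        per_k[k] = CoexprRow(
            k=k,
            n_pairs_before=len(r_b),
            mean_r_before=float(r_b.mean()) if len(r_b) else nan,
            n_pairs_after=len(r_a),
            mean_r_after=float(r_a.mean()) if len(r_a) else nan,
            t_statistic=t,
            p_value=p,
        )
    return CoexprReport(per_k)
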