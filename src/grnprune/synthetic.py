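"""Synthetic benchmark generator with known ground truth.

Builds a toy genome whose peak-to-TSS distances are controlled, and an
expression matrix generated from a known linear TF -> gene model, so that
every stage of the pipeline — assignment, pruning, validation — can be
checked against the generative truth without any external download.

The generative model:

* every gene (TF or target) sits on a synthetic chromosome with neighbours
  spaced more than twice the assignment threshold apart, so a peak placed
  near one TSS can never be assigned to another gene;
* each target gene gets ``true_per_gene`` true regulators (nonzero linear
  weights) and ``decoys_per_gene`` decoy TFs whose peaks also fall inside
  the window but which never enter the expression model — exactly the
  false assignments pruning should remove;
* TF expression profiles load on a small set of shared latent factors plus
  independent noise, inducing a realistic spread of TF-TF correlations;
  each target is the weighted sum of its true regulators' standardized
  profiles plus Gaussian noise, then the whole matrix is shifted/scaled to
  a non-negative counts-like range (an affine map, so correlations and
  tree splits are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    ExpressionMatrix,
    Gene,
    GenomicInterval,
    Peak,
    RegulatoryNetwork,
    SyntheticTruth,
)

#: the standard benchmark configuration: 25 TFs, 150 target genes, 3 true
#: regulators + 12 decoy candidates per gene, 400 samples.
STANDARD_PRESET = dict(
    n_tfs=25,
    n_genes=150,
    true_per_gene=3,
    decoys_per_gene=12,
    threshold_nt=1500,
    n_samples=400,
)

_PEAK_WIDTH = (100, 400)  # nt, inclusive range
_SPACING_MARGIN = 2000  # nt beyond the 2x-threshold no-cross-talk bound
_GENE_LENGTH = 1000  # nominal annotated gene body length


def simulate_genome(
    n_tfs: int,
    n_genes: int,
    true_per_gene: int,
    decoys_per_gene: int,
    threshold_nt: int,
    seed: int,
    noise_sd: float = 1.0,
    n_chromosomes: int = 3,
) -> tuple[list[Gene], list[Peak], SyntheticTruth]:
    """Generate genes, peaks at controlled TSS distances, and ground truth.

    Peaks for each target gene's true regulators and decoys are placed with
    interval-to-TSS distance uniform in [0, threshold_nt], so distance
    assignment at ``threshold_nt`` recovers exactly true + decoy candidate
    sets.  Gene spacing exceeds 2 x threshold + peak width, preventing
    cross-talk between neighbouring genes.
    """
    if min(n_tfs, n_genes, true_per_gene, threshold_nt) <= 0 or decoys_per_gene < 0:
        raise ValueError("all counts and the threshold must be positive")
    if true_per_gene + decoys_per_gene > n_tfs:
        raise ValueError(
            f"true_per_gene + decoys_per_gene = {true_per_gene + decoys_per_gene} "
            f"exceeds n_tfs = {n_tfs}"
        )
    spacing = 2 * threshold_nt + _SPACING_MARGIN
    if spacing <= 2 * threshold_nt + _PEAK_WIDTH[1]:
        raise ValueError("infeasible gene spacing for the requested threshold")

    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    target_ids = [f"G{i + 1:04d}" for i in range(n_genes)]

    genes: list[Gene] = []
    all_ids = tf_ids + target_ids
    per_chrom = -(-len(all_ids) // n_chromosomes)  # ceil division
    tss_of: dict[str, tuple[str, int]] = {}
    for idx, gid in enumerate(all_ids):
        chrom = f"chrS{idx // per_chrom + 1}"
        slot = idx % per_chrom
        tss = spacing * (slot + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(gid, chrom, strand, tss, is_tf=gid in set(tf_ids)))
        tss_of[gid] = (chrom, tss)

    peaks: list[Peak] = []
    true_edges: dict[tuple[str, str], float] = {}
    decoys: dict[str, frozenset[str]] = {}
    for gid in target_ids:
        chosen = rng.choice(n_tfs, size=true_per_gene + decoys_per_gene, replace=False)
        true_tfs = [tf_ids[i] for i in chosen[:true_per_gene]]
        decoy_tfs = [tf_ids[i] for i in chosen[true_per_gene:]]
        decoys[gid] = frozenset(decoy_tfs)
        for tf in true_tfs:
            true_edges[(tf, gid)] = float(rng.uniform(0.75, 1.5))
        chrom, tss = tss_of[gid]
        for tf in true_tfs + decoy_tfs:
            peaks.append(_place_peak(rng, chrom, tss, tf, threshold_nt))

    truth = SyntheticTruth(
        true_net=RegulatoryNetwork(true_edges.keys(), label="true"),
        weights=true_edges,
        noise_sd=noise_sd,
        decoy_candidates=decoys,
        tf_ids=tuple(tf_ids),
        target_ids=tuple(target_ids),
    )
    return genes, peaks, truth


def _place_peak(rng, chrom: str, tss: int, tf: str, threshold_nt: int) -> Peak:
    """One peak whose minimum distance to ``tss`` is uniform in [0, threshold]."""
    width = int(rng.integers(_PEAK_WIDTH[0], _PEAK_WIDTH[1] + 1))
    d = int(rng.integers(0, threshold_nt + 1))
    if d == 0:
        start = tss - width // 2
    elif rng.random() < 0.5:
        start = tss + d  # downstream: nearest edge is `start`
    else:
        start = tss - d - (width - 1)  # upstream: nearest edge is `end - 1`
    start = max(start, 0)
    return Peak(GenomicInterval(chrom, start, start + width), tf)


def simulate_expression(
    truth: SyntheticTruth,
    n_samples: int,
    seed: int,
    n_factors: Optional[int] = None,
) -> ExpressionMatrix:
    """Expression for all TFs and targets under the linear-Gaussian model."""
    if n_samples < 50:
        raise ValueError(f"need >= 50 samples, got {n_samples}")
    if not truth.tf_ids:
        raise ValueError("truth carries no TF ids")
    rng = np.random.default_rng(seed)
    n_tfs = len(truth.tf_ids)
    if n_factors is None:
        n_factors = max(2, n_tfs // 5)

    factors = rng.standard_normal((n_factors, n_samples))
    loadings = rng.uniform(0.35, 0.9, size=n_tfs)
    assignment = rng.integers(0, n_factors, size=n_tfs)
    eps = rng.standard_normal((n_tfs, n_samples))
    tf_profiles = (
        loadings[:, None] * factors[assignment]
        + np.sqrt(1.0 - loadings[:, None] ** 2) * eps
    )
    # standardize so weights act on unit-variance regressors
    tf_z = (tf_profiles - tf_profiles.mean(axis=1, keepdims=True)) / tf_profiles.std(
        axis=1, keepdims=True
    )
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}

    targets = np.zeros((len(truth.target_ids), n_samples))
    for row, gid in enumerate(truth.target_ids):
        signal = np.zeros(n_samples)
        for tf in truth.true_net.regulators_of(gid):
            signal += truth.weights[(tf, gid)] * tf_z[tf_index[tf]]
        targets[row] = signal + truth.noise_sd * rng.standard_normal(n_samples)

    mat = np.vstack([tf_z, targets])
    mat = (mat - mat.min()) * 10.0  # affine shift to a counts-like positive range
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    return ExpressionMatrix.from_arrays(
        list(truth.tf_ids) + list(truth.target_ids), sample_ids, mat
    )


@dataclass(frozen=True)
class Recovery:
    """Edge-level recovery of the generative truth."""

    precision: Optional[float]  # None when the evaluated network is empty
    recall: float
    n_true_positive: int
    n_predicted: int
    n_true: int


def evaluate_recovery(net: RegulatoryNetwork, truth: SyntheticTruth) -> Recovery:
    """Precision and recall of a network's edges against the true network."""
    true_edges = truth.true_net.edges
    tp = len(net.edges & true_edges)
    precision = tp / len(net.edges) if net.edges else None
    recall = tp / len(true_edges) if true_edges else 0.0
    return Recovery(precision, recall, tp, len(net.edges), len(true_edges))


def coregulation_ppi(truth: SyntheticTruth) -> "InteractionNetwork":
    """The truth-derived interaction network: TF pairs that truly co-regulate
    at least one gene — the synthetic analogue of a curated TF-TF PPI."""
    from itertools import combinations

    from .model import InteractionNetwork

    edges = set()
    for gid in truth.target_ids:
        regs = sorted(truth.true_net.regulators_of(gid))
        for a, b in combinations(regs, 2):
            edges.add((a, b))
    return InteractionNetwork(edges, nodes=truth.tf_ids, source_label="true_coregulation")


def standard_instance(seed: int, **overrides):
    """Generate the standard preset end to end: (genes, peaks, truth, expr)."""
    cfg = dict(STANDARD_PRESET)
    cfg.update(overrides)
    n_samples = cfg.pop("n_samples")
    genes, peaks, truth = simulate_genome(seed=seed, **cfg)
    expr = simulate_expression(truth, n_samples=n_samples, seed=seed + 1)
    return genes, peaks, truth, expr
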