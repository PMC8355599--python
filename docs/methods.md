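# Methods

This note records the modelling choices behind `grnprune`: what each stage
computes, the defaults and why, what the synthetic benchmark does and does
not emulate, and the numerical corner cases.

## Coordinates and input conventions

All genomic positions are held internally as 0-based half-open intervals
(the BED convention). BED peaks are read verbatim; GTF/GFF gene records
(1-based inclusive) are converted on read: TSS = start − 1 on the + strand,
end − 1 on −. Exactly one TSS is taken per gene-level record; collapsing
multiple transcripts to a gene-level TSS is left to the annotation,
matching gene-level count matrices. TF identity in peak files comes either
from a per-file flag or a per-row name column, since both layouts occur in
public ChIP-Seq exports.

## Step 1 — distance assignment

Edge (f, g) is created iff some peak of TF f has interval-to-point distance
≤ d from g's TSS, where the distance is 0 if the TSS lies inside the peak
and otherwise the gap to the nearest covered base. Choices worth noting:

* **Interval anchor, not midpoint.** Measuring from the peak boundary is
  the most inclusive reading and makes threshold nestedness exact:
  edges(d₁) ⊆ edges(d₂) whenever d₁ ≤ d₂. A midpoint anchor is available
  (`anchor="midpoint"`) for sensitivity analyses.
* **Symmetric window.** Upstream and downstream of the TSS count equally;
  regulatory elements sit on both sides.
* **Unweighted edges.** Multiple qualifying peaks of one TF collapse to a
  single edge.

The implementation sorts TSSs per chromosome and binary-searches the window
per peak (O(P log G + hits)); its contract is defined by, and tested
against, the exhaustive all-pairs oracle.

Network summaries define avg. indegree = edges ÷ distinct targets and
avg. outdegree = edges ÷ TFs with ≥ 1 out-edge, so each average times its
denominator reproduces the edge count exactly. Published tables of this
kind do not always use recoverable denominators; these definitions are the
self-consistent choice.

## Step 2 — forest pruning

Per target gene, candidates are its step-1 regulators present in the
expression matrix (never the gene itself). The target vector is
standardized to zero mean and unit variance — required for importances to
be comparable across genes — while candidate rows are used raw: tree
splits are invariant to monotone predictor scaling, so standardizing the
predictors would change nothing (covered by a test). Expression counts are
otherwise used as provided, without normalization.

The ensemble: `n_trees` regression trees, each grown on a bootstrap
resample, drawing `k_split` random candidates per node and taking the best
variance-reducing split. Importance of a candidate is the mean over trees
of the total sample-weighted variance reduction at its split nodes
(unnormalized mean decrease in impurity). This is delegated to
scikit-learn's `RandomForestRegressor` with per-tree
`compute_feature_importances(normalize=False)`, which computes exactly
that quantity.

Defaults, with rationale:

| parameter | default | why |
| --- | --- | --- |
| `n_trees` | 1000 | production-grade variance of the importance estimates; 100 is adequate at simulation scale and is what the test suite uses |
| `k_split` | ⌈√p⌉ | the standard regression-forest default |
| `min_samples_split` | 2 | fully grown trees; importance noise is handled by the ensemble size |
| `relevance_fraction` | 0.1 | a TF is removed iff its importance is *strictly below* 10% of the gene's maximum, so a score exactly at the cutoff is kept and the top TF always survives |
| `seed` | 0 | per-gene seeds are `blake2b(seed ":" gene_id) mod 2³¹`, making results independent of gene iteration order and safe to parallelize or resume |

Drop rules: targets absent from the expression matrix, with constant
expression (detected exactly via zero peak-to-peak range — a float `std`
of a constant vector can be rounding-noise positive), or whose only
candidate is themselves are removed entirely. This is what shrinks node
counts between reference and pruned networks. Self-prediction is
meaningless, hence the self-candidate exclusion.

Guarantees that follow: the pruned edge set is always a subset of the
reference edge set; every retained gene keeps at least one regulator; and
identical inputs plus seed give bit-identical networks.

## Validation

**Connectance.** For a gene with regulator set R (|R| = n ≥ 2) and an
undirected TF-TF interaction network, ρ = |interactions within R| /
(n(n−1)/2). Regulators missing from the interaction resource stay in the
denominator: incomplete interaction coverage should depress ρ, not
silently shrink the set. Genes with n < 2 in either network are excluded
from the better/worse/equal fractions and reported separately — including
them in "equal" would manufacture ties out of undefined values. Equality
of ρ before vs after is exact (both are rationals with known
denominators).

**Correlation networks.** TF-TF edges where Pearson r ≥ t, positive
convention by default (co-regulating TFs are expected to be co-expressed,
not anti-expressed); an |r| mode exists. Nodes are TFs with ≥ 1 retained
edge, which is why node counts shrink as t rises. STRING-style scored
tables are thresholded per evidence channel after rescaling 0–1000 integer
scores to 0–1.

**Co-expression of co-regulated pairs.** For k = 2..k_max, the pair sets
are cumulative (targets sharing *at least* k regulators) in each network
separately; per-pair Pearson r over all samples; Welch's unequal-variance
t-test compares the after-pairs' r values against the before-pairs',
oriented after − before. Welch rather than pooled-variance because the two
pair sets differ in size and spread. No multiple-testing correction is
applied across k; raw p-values are reported with a reference two-sided
significance level of 5 × 10⁻⁴. A k with fewer than two usable pairs on
either side yields NaN statistics rather than an error.

## Subnetworks

`ego_out(net, c)` returns the induced subgraph on {c} ∪ out-neighbors(c):
all edges among those nodes are kept, including regulation between the
center's targets and edges from targets back into the center. This is the
reading consistent with ego networks whose edge counts exceed their node
counts, and it makes the operation idempotent. `restrict_targets(net,
keep)` keeps an edge iff its target is in `keep` *or is itself a TF of the
network* — the regulatory cascade among TFs is always retained, because a
gene-list restriction (e.g. to mitochondrially annotated genes) is about
the non-TF leaves, not the regulators.

## Synthetic benchmark

`simulate_genome` places TF and target genes on synthetic chromosomes with
spacing 2 × threshold + 2000 nt, so no peak can reach a neighboring gene's
window at the simulated threshold. Each target gets `true_per_gene` true
regulators and `decoys_per_gene` decoy TFs; one peak per candidate is
placed with interval-to-TSS distance uniform in [0, threshold] (width
100–400 nt, upstream/downstream at random), so distance assignment at that
threshold recovers exactly the recorded candidate sets — a cross-check the
tests enforce.

`simulate_expression` draws TF profiles from ~n_tfs/5 shared latent
factors with loadings U(0.35, 0.9) plus independent noise, giving a
realistic spread of TF-TF correlations (without this, co-expression
networks at thresholds 0.25–0.85 would be degenerate, and decoys would be
trivially easy to remove). Each target is Σ w·TF (weights U(0.75, 1.5) on
standardized TF profiles) plus Gaussian noise with `noise_sd` = 1.0 — a
signal-to-noise ratio at which true regulators dominate but correlated
decoys survive often enough to keep the problem honest. The matrix is then
shifted/scaled affinely to a non-negative counts-like range, which changes
neither correlations nor tree splits.

The standard preset is 25 TFs, 150 targets, 3 true + 12 decoy candidates
per gene, 1.5 kb window, 400 samples. At these settings (100 trees) the
pruned network reaches precision ≈ 0.28–0.32 from the reference's 0.200 at
recall 1.0, and more genes gain regulator connectance against the true
co-regulation network than lose it — the package's central claims in
miniature, recomputed by `scripts/acceptance.py` and the acceptance tests.
These problem sizes keep a full multi-seed evaluation in the minutes
range on a single core.

What the benchmark does **not** emulate: negative-binomial count noise and
library-size effects, ChIP-Seq peak-calling noise, repressive (negative)
regulation, TF–TF combinatorial logic, and overlapping regulatory windows
between neighboring genes. Passing recovery bounds here therefore shows
the machinery is correct and well-calibrated under a linear-Gaussian
world, not that the same precision would be reached on real tissue
compendia.

## Degenerate inputs and numerics

* Empty gene catalogs, empty importance tables, and unknown output formats
  raise; unknown chromosomes in peak files skip the peak with a warning.
* Zero-variance rows (targets or TFs) are detected by exact constant check
  and dropped/excluded with a warning, never silently divided by.
* Importance ties are broken by candidate id in rankings; edge files are
  written in sorted order so equal networks are byte-identical on disk.
* The pipeline manifest hashes a canonical config form that excludes the
  output directory (it locates results but does not influence them) and
  records a SHA-256 per output file; re-running the same config and seed
  reproduces every digest.

## Known limitations

* Pruning cost is one forest per gene; at compendium scale (tens of
  thousands of genes × 1000 trees) this wants the resumable CLI mode and
  a few hours, not the seconds of the simulation scale.
* The 10% relevance cutoff is relative to each gene's top score; genes
  whose candidates are all irrelevant still keep their best-scoring TF.
  The method can only remove false positives among *assigned* TFs — it
  never recovers a regulator the distance step missed.
* HDF5 expression archives are not read directly; export to TSV first.
* Interaction networks are taken as given; no attempt is made to correct
  for their ascertainment biases.
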