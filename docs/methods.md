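# Methods

This note documents the models and procedures implemented in `duobin`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Feature extraction

**Length filter.** Contigs shorter than `min_length` (default 1000 bp,
inclusive) are dropped: 4-mer statistics on shorter fragments are too noisy
to act as a species signature. The boundary is inclusive because a contig
of exactly the cutoff length already carries the intended signal.

**GC content** is (#G + #C)/(#A + #C + #G + #T). Ambiguous bases are
excluded from numerator and denominator; a 4-mer window containing any
non-ACGT base is skipped entirely. Skipping, rather than imputing, avoids
biasing composition for contigs with assembly gaps.

**Tetranucleotide profile.** All 4-bp windows of the contig are counted in
a 1-bp sliding window, and each 4-mer is pooled with its reverse complement
under the lexicographically smaller (canonical) key. Counting the contig
together with its reverse complement makes the 256-vector exactly
symmetric, so the 136 canonical frequencies carry identical information at
half the dimension; the emitted vector is normalised to sum to 1. The test
suite checks this equivalence against an explicit 256-mer
contig-plus-reverse-complement counting oracle, exactly.

**Coverage** is consumed from a user-supplied table (mean reads per base)
and clustered on the natural-log scale. The log base is immaterial — it
rescales one axis and is absorbed by the per-axis standardisation that
follows. Contigs with zero coverage are excluded with a logged warning
rather than given a pseudocount: log coverage is undefined there, a
pseudocount would place such contigs at an arbitrary point of the abundance
axis, and the exclusion is accounted in the run summary.

## Primary binning (DBSCAN in GC-log-coverage space)

GC ∈ [0,1] and log coverage (≈ 0–5.7 for coverages 1–300) are
incommensurate, so each axis is standardised to zero mean and unit
population variance before Euclidean distances are computed. A constant
axis is mapped to zeros with a warning.

DBSCAN is implemented in-package with a brute-force O(n²) neighbour search:
target inputs are ≤ ~10⁵ contigs, where exactness and auditability beat an
index. A point is *core* when its ε-neighbourhood (itself included) holds
at least `min_points` points (default 4, the classic 2-D heuristic);
clusters are grown from core points in input order, so border points join
the first cluster that discovers them and runs are deterministic. The
partition of core points is order-invariant (tested against an independent
ε-graph connected-components oracle); border-point ties are the only
order-dependent detail, which the fixed scan order pins down.

**ε selection.** When not supplied, ε is read off the k-distance curve with
k = `min_points`: distances from each point to its (k−1)-th nearest other
point are sorted ascending and ε is taken at the knee, located as the point
of maximum perpendicular distance to the chord joining the curve's
endpoints. The value is floored at 1e−6 to survive duplicate-only input. A
user-supplied ε always overrides.

## Refinement (PCA + DPGMM per bin)

Bins with at least `2 * min_bin_size` contigs are re-clustered on
composition; smaller bins pass through (refining a handful of points is
meaningless) and are then subject to the same final size filter.

**PCA.** TNF profiles are mean-centred and projected onto the smallest
number of leading principal components reaching `variance_threshold`
(default 0.90) cumulative explained variance, capped at
min(10, n−1, 136). Degenerate inputs (n < 2, or zero variance) pass the bin
through unrefined. The deterministic full-SVD solver is used.

**DPGMM by collapsed Gibbs.** The Dirichlet-process mixture uses a
conjugate base measure — Normal–inverse-Wishart for d ≤ 8, independent
per-dimension Normal–inverse-χ² above (`covariance='auto'`) — so component
parameters are marginalised and each sweep reassigns every contig from its
exact conditional: occupancy × Student-t posterior predictive for existing
components, α × prior predictive for a new one. Hyperparameters are weakly
informative and empirical: prior mean = data mean, prior scale = diagonal
data variances (the prior expects one broad component spanning the data),
κ₀ = 0.01, ν₀ = d + 2. A simulation study during development compared
prior-scale multipliers {1, 0.5, 0.25, 0.1}: the broad default was the only
setting that recovered k on separated mixtures, kept genuinely single
populations whole, *and* did not fragment pure bins, so it stands.

α gets a vague Gamma(1,1) prior resampled every sweep with the
Escobar–West auxiliary-variable move; a fixed α can be configured instead.
Sweep 0 initialises by sequential predictive (CRP-style) assignment, capped
at `max_components_init` (default 20) components. Defaults are 300 sweeps
with 100 discarded as burn-in. The reported clustering is the
maximum-a-posteriori sample (CRP prior × component marginal likelihoods)
among post-burn-in sweeps — simpler and more reproducible than a consensus
matrix, and deterministic given the seed. Per-bin seeds are derived from
the run seed via `SeedSequence`, so the pipeline is reproducible end to
end. Gibbs sampling was chosen over variational inference deliberately:
the sampler targets the exact posterior, and bin-level problem sizes make
its cost immaterial.

The predictive and marginal-likelihood kernels are numba-compiled; the test
suite verifies them against independent scipy multivariate-t closed forms
to 1e−10.

**Small-bin filter.** Output bins smaller than `min_bin_size` (default 5
contigs) are dissolved to *unclassified*. Together with DBSCAN noise this
is the package's deliberate recall-for-precision trade; every dissolved or
noise contig is itemised in `summary.json`.

Refinement never merges: contigs from different primary bins cannot share a
final bin, and the pipeline conserves contigs exactly
(classified + unclassified = input), both enforced by tests.

## Evaluation measures

Precision, recall, F1 and species discovery are defined in the README. Two
policies are worth stating:

* **Counting unit** is the contig (unweighted). Equations of this form are
  sometimes written over reads; the workflow never sees reads, so contigs
  are the honest unit. A weighted mode (e.g. by contig length) is available
  (`--bp-weighted`) for sensitivity analysis.
* **Genome totals** for the > 50 %/> 50 % discovery rule include contigs
  the pipeline filtered out (when the truth table covers them), so
  aggressive filtering cannot inflate discovery; `--evaluated-only`
  restricts totals to contigs present in the assignment.

The 50 % conditions are strict inequalities; a genome split exactly 50/50
is not discovered. At most one bin can hold > 50 % of a genome, so each
genome is discovered by at most one bin.

## Synthetic communities

The generator is first-class, tested code; it defines the conditions under
which every end-to-end claim in this package is demonstrated.

* **Genomes** (default 100 kbp — a desk-scale stand-in for complete
  genomes) are sampled from per-genome Markov chains of order 3, the order
  that directly shapes 4-mer statistics. Each genome's per-context emission
  probabilities are Dirichlet draws (concentration 60 around base
  probabilities implied by the genome's target GC) renormalised so G+C is
  emitted with exactly the target probability in every context — the
  stationary GC therefore matches its target up to binomial noise, while
  the context structure stays genome-specific. Target GCs are drawn
  uniformly from (0.30, 0.70) per species.
* **Strains** are emulated by mixing a strain's transition table with its
  group's shared parent table (`strain_epsilon`, 0 = identical strains), so
  strain groups share composition but can differ in abundance.
* **Contigs** fragment each genome left to right with lengths uniform in
  (1000, 20000) bp; the trailing remainder below the minimum is dropped, so
  the fragments reconstruct a genome prefix. Ids encode the source genome;
  the truth table is emitted alongside.
* **Coverage**: k distribution centres are drawn uniformly in (1, 300);
  genomes are assigned to centres round-robin (as even a partition as
  possible); each contig's coverage is its genome's centre times lognormal
  noise (σ = 0.1), clipped back into range. The benchmark grid runs
  k ∈ {1, 2, 3, 5, 6, 10, 15, 30} with 10 replicates each (80 datasets);
  replicate seeds are derived deterministically from the base seed and
  recorded in the manifest, and regeneration from a seed is byte-identical.

**What passing on this generator shows — and what it does not.** The
generator produces genuinely species-specific composition, strain structure
and abundance separation, so it exercises the entire two-tier logic. It
does **not** model sequencing error, chimeric or repeat-collapsed contigs,
within-genome compositional heterogeneity, or skewed real-world GC
distributions; results on it bound what the method can do when its
assumptions hold, not what it will do on an arbitrary real assembly.

## Problem sizes and numerical choices

End-to-end demonstrations use 30 genomes × 100 kbp (≈ 300 contigs per
dataset), 3 replicates per coverage-distribution setting in the test suite
and 2 in the acceptance script — sizes chosen so the full suite re-runs in
minutes while keeping every per-dataset step (DBSCAN at n ≈ 300, per-bin
DPGMM at n ≤ 300, d ≤ 10) at realistic per-bin scale. The sampler's
Cholesky factorisations floor pivots at 1e−300; data variances used for the
prior are floored to guard zero-variance dimensions; categorical draws use
the max-shifted exponential form. All stochastic stages flow from one run
seed (sub-seeds via `SeedSequence`), and reruns are byte-identical.

## Known limitations

* DBSCAN with a single global ε assumes clusters of comparable density in
  GC-log-coverage space; communities whose abundance structure creates
  densities differing by orders of magnitude will need a manually chosen ε
  or will lose sparse populations to noise.
* Recall is deliberately sacrificed: unclassified contigs are reported, not
  rescued. Reassigning them to high-precision bins is future work.
* The DPGMM assumes approximately Gaussian TNF scores per species within a
  bin; strains with essentially identical composition and coincident
  coverage are not separable by design.
* Single-site Gibbs updates can be slow to nucleate a split when the
  compositional difference between merged species is marginal; with the
  defaults this shows up as occasional conservative (merged) refinements.
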