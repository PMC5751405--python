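# duobin

Two-tier, fully unsupervised binning of metagenomic contigs from a **single
sample**, using contig **coverage first** and **composition second**.

## The problem

Shotgun metagenomics yields assembled contigs from a mixture of uncultured
organisms. *Binning* groups those contigs into clusters intended to
correspond to individual genomes. Composition-based signatures
(tetranucleotide frequencies, GC content) discriminate species well — but
closely related organisms (strains) share composition, and there they fail.
Relative abundance, observable as contig coverage, often differs even
between strains. `duobin` therefore bins in two tiers:

1. **Primary binning** — each contig becomes a point in
   (GC, log coverage) space; both axes are standardised and the points are
   clustered with **DBSCAN** (Euclidean metric). DBSCAN infers the number of
   clusters, makes no shape assumption, and labels low-density points as
   noise instead of forcing them into bins. The radius `ε` defaults to the
   knee of the k-distance curve (k = `min_points`, default 4).
2. **Refinement** — each primary bin may still mix species of similar
   abundance. Its contigs' tetranucleotide frequency (TNF) profiles — 136
   canonical (strand-symmetric) 4-mer frequencies — are reduced by PCA and
   clustered with a **Dirichlet-process Gaussian mixture model (DPGMM)**
   fit by collapsed **Gibbs sampling**, which infers the number of
   sub-bins. Sub-bins smaller than `min_bin_size` are dissolved to
   *unclassified*, trading recall for precision.

Inputs are a FASTA of assembled contigs (≥ 1 kbp after filtering, by
default) and a two-column TSV of per-contig mean coverage produced by any
read aligner. Assembly and read mapping are out of scope.

### The model in brief

The refinement stage assumes TNF profiles within one species are
approximately Gaussian in the PCA-reduced space. A finite Gaussian mixture

P(y) = Σ_{j=1..k} w_j N(y | μ_j, σ_j⁻¹),  Σ_j w_j = 1

is extended with k → ∞ under a Dirichlet-process prior with concentration
α, so k need not be specified. With a conjugate Normal–inverse-Wishart base
measure the component parameters are marginalised and a collapsed Gibbs
sampler reassigns each contig i from

p(z_i = c | z_−i, y) ∝ n_c^{−i} · t_c(y_i)  (existing component c)
p(z_i = new | z_−i, y) ∝ α · t_0(y_i)     (new component),

where t_c is the Student-t posterior predictive of component c and t_0 the
prior predictive. α is resampled each sweep under a Gamma(1,1) prior. The
reported clustering is the highest-joint-posterior assignment among
post-burn-in sweeps — deterministic given the seed.

Binning quality against a ground truth (R_ij = contigs of genome j in bin
i, U = unclassified contigs):

- Precision (%) = 100 · Σ_i max_j R_ij / Σ_ij R_ij
- Recall (%)  = 100 · Σ_j max_i R_ij / (Σ_ij R_ij + U)
- F1 = 2·P·R / (P + R)
- genome S is *discovered* when one bin holds > 50 % of S's contigs and is
  > 50 % composed of them.

## Worked example

Simulate a small 5-species community with known ground truth, bin it, and
score the result:

```sh
$ duobin simulate --n-genomes 5 --n-coverage-distributions 5 --seed 11 --out sim
$ duobin bin --contigs sim/contigs.fasta --coverage sim/coverage.tsv --out run --seed 11
{"input_contigs": 52, "too_short": 0, "zero_coverage": 0, "evaluated": 52, "classified": 32, "unclassified": 20}
$ duobin evaluate --assignments run/assignments.tsv --truth sim/truth.tsv
precision	recall	f1	n_species_discovered
96.8750	59.6154	73.8095	4
```

The run directory contains one FASTA per bin (`bin_000.fasta`, … ordered by
size), `unclassified.fasta`, the per-contig `assignments.tsv` and
`features.tsv`, and `summary.json` with stage-by-stage contig accounting.
Here 32 of 52 contigs were classified into bins that are 96.9 % pure; the
20 noise/dissolved contigs depress recall to 59.6 % — the deliberate
precision-over-recall trade of the two-tier design — and 4 of the 5 genomes
are recovered under the strict > 50 %/> 50 % rule.

The same functionality is available as a library of sklearn-style
estimators:

```python
from duobin import (CommunitySpec, generate_community, build_feature_table,
                    CoverageCompositionBinner, evaluate_binning)

com = generate_community(CommunitySpec(n_genomes=5, n_coverage_distributions=5, seed=11))
features = build_feature_table(com.contigs, com.coverage)
binner = CoverageCompositionBinner(random_state=11).fit(features)
print(evaluate_binning(binner.assignment_, com.truth)["precision"])
```

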