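"""Synthetic metagenomic communities with known ground truth.

Genomes are simulated from per-genome Markov chains (order 3 by default, so
the chains directly shape tetranucleotide statistics) rather than downloaded:
each genome gets a target GC fraction and a random per-context transition
table whose G+C emission probability is renormalised to the target exactly,
giving species-distinct composition at a controlled GC. Strain structure is
emulated by deriving the members of a strain group from a shared parent
table with a small perturbation ``strain_epsilon`` — strains then share
composition but can differ in abundance, which is precisely the regime where
coverage-first binning should pay off.

Genomes are fragmented left-to-right into non-overlapping contigs with
lengths uniform in a configured range (>= 1 kbp by default), and each genome
draws its contig coverages from one of a configurable number of distinct
coverage distributions with centres in the range 1-300: the distribution
centres are sampled uniformly from that range, genomes are split as evenly
as possible among them, and per-contig coverages are the centre times
multiplicative lognormal noise, clipped back into the range.

The benchmark suite reproduces the coverage-distribution experiment design:
for each number of distinct coverage distributions in {1, 2, 3, 5, 6, 10,
15, 30} a set of replicate communities is generated (10 by default, i.e. 80
datasets).

What this emulates — and what it does not: real assemblies have chimeras,
uneven fragment lengths, repeat-collapsed coverage and sequencing error;
none of those are modelled here (see the methods note).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .io import ContigRecord, _write_fasta

#: the distribution counts of the coverage-distribution experiment
BENCHMARK_DISTRIBUTION_COUNTS = (1, 2, 3, 5, 6, 10, 15, 30)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_SEED = 2**31 - 1


@dataclass
class CommunitySpec:
    """Full description of one synthetic community.

    Parameters
    ----------
    n_genomes : int
    n_coverage_distributions : int
        Number of distinct coverage distributions in {1..n_genomes}.
    coverage_range : (float, float), default (1, 300)
    contig_length_range : (int, int), default (1000, 20000)
        Uniform fragment-length range in bp.
    contigs_per_genome : int, optional
        Cap on fragments per genome; by default the whole genome is
        fragmented.
    genome_length : int, default 100000
        Desk-scale stand-in for full genomes.
    markov_order : int, default 3
        Order of the per-genome composition chain.
    gc_range : (float, float), default (0.3, 0.7)
        Per-genome (per strain group) target GC fractions are drawn
        uniformly from this range.
    strain_group_size : int, default 1
        Genomes per strain group; 1 means independent species.
    strain_epsilon : float, default 0.05
        Perturbation mixing weight between a strain's table and its group's
        parent table (0 = identical strains).
    coverage_noise_sd : float, default 0.1
        Sigma of the within-genome lognormal coverage noise.
    coverage_centers : sequence of float, optional
        Explicit distribution centres (overrides random draw).
    seed : int
    """

    n_genomes: int = 30
    n_coverage_distributions: int = 1
    coverage_range: tuple[float, float] = (1.0, 300.0)
    contig_length_range: tuple[int, int] = (1000, 20000)
    contigs_per_genome: int | None = None
    genome_length: int = 100_000
    markov_order: int = 3
    gc_range: tuple[float, float] = (0.3, 0.7)
    strain_group_size: int = 1
    strain_epsilon: float = 0.05
    coverage_noise_sd: float = 0.1
    coverage_centers: tuple[float, ...] | None = None
    dirichlet_concentration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not (1 <= self.n_coverage_distributions <= self.n_genomes):
            raise ValueError(
                "n_coverage_distributions must be in {1..n_genomes}"
            )
        lo, hi = self.coverage_range
        if not (0 < lo <= hi):
            raise ValueError("coverage_range must satisfy 0 < low <= high")
        if self.contig_length_range[0] < 1:
            raise ValueError("contig lengths must be >= 1 bp")
        if not (0 <= self.strain_epsilon <= 1):
            raise ValueError("strain_epsilon must be in [0, 1]")
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")


@dataclass
class SyntheticCommunity:
    """A generated dataset: contigs, coverage table and ground truth."""

    contigs: list[ContigRecord]
    coverage: dict[str, float]
    truth: dict[str, str]
    genomes: dict[str, str]  # genome name -> sequence
    centers: dict[str, float]  # genome name -> coverage centre
    spec: CommunitySpec


def _base_weights(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _renormalise_gc(table: np.ndarray, gc: float) -> np.ndarray:
    """Scale each context row so P(G or C | context) equals gc exactly."""
    out = table.copy()
    gc_mass = out[:, 1] + out[:, 2]
    at_mass = out[:, 0] + out[:, 3]
    gc_mass = np.maximum(gc_mass, 1e-12)
    at_mass = np.maximum(at_mass, 1e-12)
    out[:, 1] *= gc / gc_mass
    out[:, 2] *= gc / gc_mass
    out[:, 0] *= (1 - gc) / at_mass
    out[:, 3] *= (1 - gc) / at_mass
    return out


def _random_table(
    gc: float, order: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Random per-context transition table with exact GC emission."""
    n_ctx = 4**order
    alpha = concentration * _base_weights(gc)
    table = rng.dirichlet(alpha, size=n_ctx)
    return _renormalise_gc(table, gc)


@njit(cache=True)
def _markov_codes(cum, u, init_ctx, n_ctx):
    L = u.shape[0]
    out = np.empty(L, dtype=np.int64)
    ctx = init_ctx
    for i in range(L):
        r = u[i]
        row = cum[ctx]
        b = 0
        while b < 3 and r > row[b]:
            b += 1
        out[i] = b
        ctx = (ctx * 4 + b) % n_ctx
    return out


def _sequence_from_table(
    table: np.ndarray, length: int, order: int, gc: float,
    rng: np.random.Generator,
) -> str:
    n_ctx = 4**order
    w = _base_weights(gc)
    head = rng.choice(4, size=max(order, 0), p=w)
    ctx = 0
    for b in head:
        ctx = ctx * 4 + int(b)
    body = _markov_codes(
        np.cumsum(table, axis=1),
        rng.random(length - len(head)),
        ctx,
        n_ctx,
    )
    codes = np.concatenate([head.astype(np.int64), body]) if order else body
    return _BASE_BYTES[codes].tobytes().decode("ascii")


class _GenomeModels:
    """Per-genome GC targets and transition tables for one community."""

    def __init__(self, spec: CommunitySpec, rng: np.random.Generator):
        lo, hi = spec.gc_range
        if not (0 < lo <= hi < 1):
            raise ValueError(
                f"unreachable GC target range {spec.gc_range}; need 0 < GC < 1"
            )
        g = spec.strain_group_size
        n_groups = -(-spec.n_genomes // g)
        self.group_of = [i // g for i in range(spec.n_genomes)]
        self.gc = [float(rng.uniform(lo, hi)) for _ in range(n_groups)]
        parents = [
            _random_table(
                self.gc[j], spec.markov_order, spec.dirichlet_concentration, rng
            )
            for j in range(n_groups)
        ]
        self.tables = []
        for i in range(spec.n_genomes):
            j = self.group_of[i]
            if spec.strain_epsilon == 0 or g == 1:
                self.tables.append(parents[j])
            else:
                fresh = _random_table(
                    self.gc[j], spec.markov_order,
                    spec.dirichlet_concentration, rng,
                )
                mixed = (
                    (1 - spec.strain_epsilon) * parents[j]
                    + spec.strain_epsilon * fresh
                )
                self.tables.append(_renormalise_gc(mixed, self.gc[j]))

    def gc_of(self, genome_index: int) -> float:
        return self.gc[self.group_of[genome_index]]


def simulate_genome(
    spec: CommunitySpec, genome_index: int, rng: np.random.Generator,
    models: _GenomeModels | None = None,
) -> str:
    """Simulate one genome sequence from its Markov chain.

    The realised GC content is checked against the genome's target (within
    0.02); the per-context GC renormalisation makes violations essentially
    impossible at default genome lengths.
    """
    if models is None:
        models = _GenomeModels(spec, rng)
    gc = models.gc_of(genome_index)
    seq = _sequence_from_table(
        models.tables[genome_index], spec.genome_length, spec.markov_order,
        gc, rng,
    )
    realised = (seq.count("G") + seq.count("C")) / len(seq)
    # the emission GC is exact by construction; allow binomial sampling noise
    # on top of the 0.02 contract for short genomes
    tol = 0.02 + 4.0 * np.sqrt(gc * (1 - gc) / len(seq))
    if abs(realised - gc) > tol:
        raise RuntimeError(
            f"genome {genome_index}: realised GC {realised:.3f} deviates from "
            f"target {gc:.3f} by more than 0.02"
        )
    return seq


def fragment_to_contigs(
    genome: str,
    spec: CommunitySpec,
    rng: np.random.Generator,
    genome_label: str = "g000",
) -> list[ContigRecord]:
    """Cut a genome left-to-right into non-overlapping contigs.

    Fragment lengths are uniform in ``contig_length_range``; a trailing
    remainder shorter than the minimum is dropped, so the concatenation of
    the fragments reconstructs a prefix of the genome.
    """
    lo, hi = spec.contig_length_range
    if len(genome) < lo:
        raise ValueError("genome shorter than the minimum contig length")
    contigs: list[ContigRecord] = []
    pos = 0
    i = 0
    while len(genome) - pos >= lo:
        if spec.contigs_per_genome is not None and i >= spec.contigs_per_genome:
            break
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(genome) - pos)
        contigs.append(
            ContigRecord(id=f"{genome_label}_c{i:04d}", sequence=genome[pos : pos + length])
        )
        pos += length
        i += 1
    return contigs


def assign_coverages(
    spec: CommunitySpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Draw distribution centres and map genomes onto them.

    Centres are uniform in ``coverage_range`` (or taken from
    ``coverage_centers``); genome i uses centre i mod k, which partitions
    genomes as evenly as possible.
    """
    k = spec.n_coverage_distributions
    if spec.coverage_centers is not None:
        centers = np.asarray(spec.coverage_centers, dtype=float)
        if len(centers) != k:
            raise ValueError(
                "coverage_centers length must equal n_coverage_distributions"
            )
    else:
        centers = rng.uniform(*spec.coverage_range, size=k)
    mapping = [i % k for i in range(spec.n_genomes)]
    return centers, mapping


def draw_contig_coverages(
    center: float, n: int, spec: CommunitySpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-contig coverages: centre x lognormal noise, clipped to the range."""
    vals = center * rng.lognormal(0.0, spec.coverage_noise_sd, size=n)
    return np.clip(vals, *spec.coverage_range)


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate a full community (genomes, contigs, coverages, truth)."""
    rng = np.random.default_rng(spec.seed)
    models = _GenomeModels(spec, rng)
    centers, mapping = assign_coverages(spec, rng)
    contigs: list[ContigRecord] = []
    coverage: dict[str, float] = {}
    truth: dict[str, str] = {}
    genomes: dict[str, str] = {}
    center_of: dict[str, float] = {}
    for gi in range(spec.n_genomes):
        name = f"g{gi:03d}"
        seq = simulate_genome(spec, gi, rng, models=models)
        genomes[name] = seq
        frags = fragment_to_contigs(seq, spec, rng, genome_label=name)
        covs = draw_contig_coverages(
            float(centers[mapping[gi]]), len(frags), spec, rng
        )
        for rec, cov in zip(frags, covs):
            contigs.append(rec)
            coverage[rec.id] = float(cov)
            truth[rec.id] = name
        center_of[name] = float(centers[mapping[gi]])
    return SyntheticCommunity(
        contigs=contigs,
        coverage=coverage,
        truth=truth,
        genomes=genomes,
        centers=center_of,
        spec=spec,
    )


def write_community(
    community: SyntheticCommunity, outdir: str | os.PathLike
) -> dict[str, str]:
    """Write contigs.fasta, coverage.tsv, truth.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(community.contigs, outdir / "contigs.fasta")
    with open(outdir / "coverage.tsv", "w") as fh:
        fh.write("contig_id\tcoverage\n")
        for rec in community.contigs:
            fh.write(f"{rec.id}\t{community.coverage[rec.id]:.6f}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("contig_id\tgenome\n")
        for rec in community.contigs:
            fh.write(f"{rec.id}\t{community.truth[rec.id]}\n")
    spec_dict = asdict(community.spec)
    manifest = {
        "spec": spec_dict,
        "n_contigs": len(community.contigs),
        "genome_coverage_centers": community.centers,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return {
        "contigs": str(outdir / "contigs.fasta"),
        "coverage": str(outdir / "coverage.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }


def _replicate_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([base_seed, index])
    return int(ss.generate_state(1)[0] % _MAX_SEED) + 1


def benchmark_specs(
    base_spec: CommunitySpec,
    distribution_counts: tuple[int, ...] = BENCHMARK_DISTRIBUTION_COUNTS,
    replicates: int = 10,
) -> list[CommunitySpec]:
    """Specs for the coverage-distribution experiment grid.

    One spec per (distribution count, replicate); replicate seeds are
    deterministic functions of the base seed.
    """
    specs = []
    idx = 0
    for k in distribution_counts:
        for _ in range(replicates):
            specs.append(
                CommunitySpec(
                    **{
                        **asdict(base_spec),
                        "n_coverage_distributions": k,
                        "seed": _replicate_seed(base_spec.seed, idx),
                        # dataclass tuples survive asdict as lists
                        "coverage_range": tuple(base_spec.coverage_range),
                        "contig_length_range": tuple(base_spec.contig_length_range),
                        "gc_range": tuple(base_spec.gc_range),
                        "coverage_centers": base_spec.coverage_centers,
                    }
                )
            )
            idx += 1
    return specs


def generate_benchmark_suite(
    base_spec: CommunitySpec,
    outdir: str | os.PathLike,
    distribution_counts: tuple[int, ...] = BENCHMARK_DISTRIBUTION_COUNTS,
    replicates: int = 10,
) -> dict:
    """Generate and write the full benchmark grid (80 datasets by default).

    Each dataset lands in ``<outdir>/ndist<k>_rep<r>/``; a top-level
    ``manifest.json`` records the grid and every replicate seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    specs = benchmark_specs(base_spec, distribution_counts, replicates)
    i = 0
    for k in distribution_counts:
        for r in range(replicates):
            spec = specs[i]
            i += 1
            sub = outdir / f"ndist{k:02d}_rep{r:02d}"
            community = generate_community(spec)
            paths = write_community(community, sub)
            entries.append(
                {
                    "n_coverage_distributions": k,
                    "replicate": r,
                    "seed": spec.seed,
                    "paths": paths,
                }
            )
    manifest = {
        "distribution_counts": list(distribution_counts),
        "replicates": replicates,
        "n_datasets": len(entries),
        "base_seed": base_spec.seed,
        "datasets": entries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
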