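"""Compositional feature extraction for metagenomic contigs.

Contigs are summarised by three feature families that together drive the
two-tier binning workflow:

* **GC content** — the fraction of G+C among unambiguous bases; a coarse,
  species-correlated compositional signature.
* **Tetranucleotide frequency (TNF) profile** — relative frequencies of all
  4-mers counted in a 1-bp sliding window over the contig *and* its reverse
  complement. Because each 4-mer and its reverse complement always receive
  identical pooled counts, the 256-dimensional strand-symmetric vector is
  stored losslessly as 136 canonical 4-mer frequencies (the lexicographically
  smaller of each reverse-complement pair).
* **Coverage** — mean reads per base, supplied externally by the user (from a
  read aligner); stored alongside its natural logarithm, which is the scale
  on which coverage is clustered.

Contigs shorter than a length cutoff (default 1000 bp) carry weak
compositional signal and are dropped before feature computation; contigs with
zero coverage are excluded (log-coverage is undefined for them).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ContigRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default minimum contig length in bp
DEFAULT_MIN_LENGTH = 1000


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case preserved for ACGTN)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _all_tetramers() -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=4)]


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


#: the 136 canonical tetramers, sorted lexicographically
CANONICAL_TETRAMERS: tuple[str, ...] = tuple(
    sorted({_canonical(k) for k in _all_tetramers()})
)

N_CANONICAL = len(CANONICAL_TETRAMERS)  # 136 = 120 rc-pairs + 16 palindromes

# base -> 2-bit code lookup over raw byte values; ambiguous bases -> -1
_CODE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

# 256 4-mer index -> canonical index in CANONICAL_TETRAMERS
_CANON_POS = {k: i for i, k in enumerate(CANONICAL_TETRAMERS)}
_FOLD = np.array(
    [_CANON_POS[_canonical(k)] for k in _all_tetramers()], dtype=np.int64
)


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence: (#G + #C) / (#A + #C + #G + #T).

    Ambiguous bases (``N`` etc.) are excluded from numerator and denominator.

    Raises
    ------
    ValueError
        If the sequence is empty or contains no unambiguous base.
    """
    if len(sequence) == 0:
        raise ValueError("gc_content: empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("gc_content: sequence has no unambiguous (ACGT) bases")
    return gc / (gc + at)


def tetranucleotide_profile(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency profile of a sequence.

    Every 4-bp window containing only A/C/G/T is counted; each 4-mer is pooled
    with its reverse complement under the canonical (lexicographically
    smaller) key, which is equivalent to counting the contig together with its
    reverse complement. The returned vector of length 136 (ordered as
    :data:`CANONICAL_TETRAMERS`) is normalised to sum to 1.

    Raises
    ------
    ValueError
        If the sequence is shorter than 4 bp or no window is free of
        ambiguous bases.
    """
    if len(sequence) < 4:
        raise ValueError("tetranucleotide_profile: sequence shorter than 4 bp")
    codes = _CODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    ok = codes >= 0
    valid = ok[:-3] & ok[1:-2] & ok[2:-1] & ok[3:]
    if not valid.any():
        raise ValueError(
            "tetranucleotide_profile: no 4-bp window free of ambiguous bases"
        )
    idx = (
        codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    )[valid]
    counts = np.bincount(_FOLD[idx], minlength=N_CANONICAL).astype(float)
    return counts / counts.sum()


def log_transform_coverage(coverage: float) -> float:
    """Natural log of a positive coverage value.

    Raises
    ------
    ValueError
        If coverage is not strictly positive (such contigs are excluded
        upstream with a warning rather than given a pseudocount).
    """
    if coverage <= 0:
        raise ValueError("log_transform_coverage: coverage must be > 0")
    return math.log(coverage)


def filter_by_length(
    contigs: Sequence[ContigRecord], min_len: int = DEFAULT_MIN_LENGTH
) -> list[ContigRecord]:
    """Retain contigs of length >= ``min_len`` (inclusive), preserving order."""
    if min_len < 1:
        raise ValueError("filter_by_length: min_len must be >= 1")
    kept = [c for c in contigs if len(c.sequence) >= min_len]
    removed = len(contigs) - len(kept)
    if removed:
        logger.info(
            "length filter (< %d bp) removed %d of %d contigs",
            min_len,
            removed,
            len(contigs),
        )
    return kept


def build_feature_table(
    contigs: Iterable[ContigRecord],
    coverages: Mapping[str, float],
    min_len: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Length-filter contigs and assemble the per-contig feature table.

    Returns a DataFrame indexed by contig id with columns ``length``, ``gc``,
    ``coverage``, ``log_coverage`` and one column per canonical tetramer.
    Contigs shorter than ``min_len`` or with zero coverage are excluded; the
    exclusion counts are stored in ``df.attrs["exclusions"]``.

    Raises
    ------
    KeyError
        If a retained contig has no coverage entry.
    ValueError
        If no contig survives filtering.
    """
    contigs = list(contigs)
    kept = filter_by_length(contigs, min_len)
    missing = [c.id for c in kept if c.id not in coverages]
    if missing:
        raise KeyError(
            "missing coverage entries for contigs: " + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )
    zero_cov = [c.id for c in kept if coverages[c.id] <= 0]
    if zero_cov:
        logger.warning(
            "excluding %d contigs with zero coverage (log undefined): %s%s",
            len(zero_cov),
            ", ".join(zero_cov[:5]),
            "..." if len(zero_cov) > 5 else "",
        )
    usable = [c for c in kept if coverages[c.id] > 0]
    if not usable:
        raise ValueError(
            "no contigs remain after length/coverage filtering; "
            "consider lowering min_len"
        )
    rows = []
    for c in usable:
        cov = float(coverages[c.id])
        rows.append(
            (
                c.id,
                len(c.sequence),
                gc_content(c.sequence),
                cov,
                math.log(cov),
                tetranucleotide_profile(c.sequence),
            )
        )
    tnf = np.vstack([r[5] for r in rows])
    df = pd.DataFrame(
        {
            "length": [r[1] for r in rows],
            "gc": [r[2] for r in rows],
            "coverage": [r[3] for r in rows],
            "log_coverage": [r[4] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="id"),
    )
    df = pd.concat(
        [df, pd.DataFrame(tnf, index=df.index, columns=list(CANONICAL_TETRAMERS))],
        axis=1,
    )
    df.attrs["exclusions"] = {
        "input": len(contigs),
        "too_short": len(contigs) - len(kept),
        "zero_coverage": len(zero_cov),
        "retained": len(usable),
    }
    return df


def tnf_matrix(features: pd.DataFrame) -> np.ndarray:
    """Extract the n x 136 TNF matrix from a feature table."""
    return features[list(CANONICAL_TETRAMERS)].to_numpy(dtype=float)
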