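"""Binning performance measures against a ground truth.

With N genomes and M output bins, let R_ij be the number of contigs in bin
C_i originating from genome j, and U the number of unclassified contigs.

* precision (%) = 100 * sum_i max_j R_ij / sum_ij R_ij — average bin purity;
  unclassified contigs do not enter.
* recall (%) = 100 * sum_j max_i R_ij / (sum_ij R_ij + U) — genome
  completeness, honestly penalising unclassified contigs.
* F1 (%) = harmonic mean of precision and recall.
* species discovered: genome S counts as discovered when some bin C holds
  strictly more than 50% of S's contigs and strictly more than 50% of C's
  contigs come from S.

Counting is per contig by default (the workflow operates on contigs); an
optional weighting (e.g. by contig length in bp) is available for
sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UNCLASSIFIED

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts of contigs per (bin, genome) plus the unclassified total."""

    R: np.ndarray  # shape (M, N)
    bins: list[int]  # row labels
    genomes: list[str]  # column labels
    unclassified: float

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if (self.R < 0).any() or self.unclassified < 0:
            raise ValueError("ConfusionMatrix: counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.R.sum() + self.unclassified)


def _as_mapping(predicted) -> Mapping[str, int]:
    if isinstance(predicted, pd.Series):
        return predicted.to_dict()
    return predicted


def confusion_matrix(
    predicted,
    truth: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> ConfusionMatrix:
    """Tally contigs per (bin, genome); unclassified counted separately.

    Parameters
    ----------
    predicted : mapping or Series
        Contig id -> bin label (UNCLASSIFIED for noise).
    truth : mapping
        Contig id -> genome id; must cover every predicted contig.
    weights : mapping, optional
        Contig id -> weight (defaults to 1 per contig; pass lengths for a
        base-pair-weighted evaluation).
    """
    predicted = _as_mapping(predicted)
    missing = [cid for cid in predicted if cid not in truth]
    if missing:
        raise KeyError(
            "contigs missing from ground truth: " + ", ".join(sorted(missing)[:20])
        )
    bins = sorted({b for b in predicted.values() if b != UNCLASSIFIED})
    genomes = sorted({truth[cid] for cid in predicted})
    brow = {b: i for i, b in enumerate(bins)}
    gcol = {g: j for j, g in enumerate(genomes)}
    R = np.zeros((len(bins), len(genomes)))
    unclassified = 0.0
    for cid, b in predicted.items():
        w = 1.0 if weights is None else float(weights[cid])
        if b == UNCLASSIFIED:
            unclassified += w
        else:
            R[brow[b], gcol[truth[cid]]] += w
    return ConfusionMatrix(R=R, bins=bins, genomes=genomes, unclassified=unclassified)


def precision(cm: ConfusionMatrix) -> float:
    """Overall binning precision in percent; NaN if nothing was classified."""
    tot = cm.R.sum()
    if tot == 0:
        logger.warning("precision undefined: no classified contigs")
        return math.nan
    return 100.0 * cm.R.max(axis=1).sum() / tot


def recall(cm: ConfusionMatrix) -> float:
    """Overall binning recall in percent (unclassified in the denominator)."""
    denom = cm.R.sum() + cm.unclassified
    if denom == 0:
        raise ValueError("recall: empty evaluation set")
    if cm.R.size == 0:
        return 0.0
    return 100.0 * cm.R.max(axis=0).sum() / denom


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent); 0 when both are 0."""
    if precision_pct < 0 or recall_pct < 0:
        raise ValueError("f1: negative input")
    if precision_pct + recall_pct == 0:
        logger.info("f1: precision = recall = 0, returning 0 by convention")
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def species_discovered(
    cm: ConfusionMatrix,
    predicted,
    truth: Mapping[str, str],
    include_filtered: bool = True,
) -> dict[str, tuple[float, float]]:
    """Genomes discovered under the strict >50%/>50% rule.

    Genome S is discovered by bin C when strictly more than half of C's
    contigs come from S and strictly more than half of S's contigs sit in C.
    By default a genome's total |S| counts every contig the truth table
    assigns to it — including contigs that were filtered out before binning —
    which penalises filtering honestly; set ``include_filtered=False`` to
    restrict |S| to contigs present in the prediction.

    Returns
    -------
    dict
        genome -> (per-species precision %, % of the genome's contigs binned),
        both computed from the discovering bin.
    """
    predicted = _as_mapping(predicted)
    if include_filtered:
        totals = {g: 0.0 for g in cm.genomes}
        for cid, g in truth.items():
            if g in totals:
                totals[g] = totals.get(g, 0.0) + 1.0
    else:
        totals = {g: 0.0 for g in cm.genomes}
        for cid in predicted:
            totals[truth[cid]] += 1.0

    discovered: dict[str, tuple[float, float]] = {}
    bin_sizes = cm.R.sum(axis=1)
    for j, g in enumerate(cm.genomes):
        size_s = totals[g]
        if size_s == 0:
            continue
        for i in range(len(cm.bins)):
            r = cm.R[i, j]
            if r > 0.5 * bin_sizes[i] and r > 0.5 * size_s:
                discovered[g] = (
                    100.0 * r / bin_sizes[i],
                    100.0 * r / size_s,
                )
                break  # at most one bin can hold >50% of S
    return discovered


def evaluate_binning(
    predicted,
    truth: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
    include_filtered: bool = True,
) -> dict:
    """All four measures in one call: P, R, F1 (percent) and species count."""
    cm = confusion_matrix(predicted, truth, weights=weights)
    p = precision(cm)
    r = recall(cm)
    disc = species_discovered(cm, predicted, truth, include_filtered=include_filtered)
    return {
        "precision": p,
        "recall": r,
        "f1": f1(0.0 if math.isnan(p) else p, r),
        "n_species_discovered": len(disc),
        "species": disc,
        "confusion": cm,
    }
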