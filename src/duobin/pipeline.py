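"""End-to-end binning: features -> primary DBSCAN -> DPGMM refinement -> files.

The top-level estimator :class:`CoverageCompositionBinner` composes the two
tiers over a feature table and follows the scikit-learn clusterer protocol
(``fit`` / ``fit_predict`` / ``labels_``), so it can sit in sklearn tooling.
:func:`run_pipeline` wraps it with file I/O, stage-by-stage error reporting
and a run summary whose contig accounting (short + zero-coverage + classified
+ unclassified = input) is the primary debugging surface.

A single mandatory seed governs every stochastic stage; reruns with the same
inputs, configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from . import io
from .cluster import DEFAULT_MIN_POINTS, primary_bin
from .features import DEFAULT_MIN_LENGTH, build_feature_table
from .io import UNCLASSIFIED
from .refine import RefinementConfig, refine_bins

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error raised by a named stage of the pipeline."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input paths."""

    min_length: int = DEFAULT_MIN_LENGTH
    epsilon: float | None = None
    min_points: int = DEFAULT_MIN_POINTS
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    seed: int = 0
    outdir: str = "duobin_out"

    def __post_init__(self) -> None:
        # the run seed governs refinement as well
        self.refinement = dataclasses.replace(self.refinement, seed=self.seed)


class CoverageCompositionBinner(BaseEstimator, ClusterMixin):
    """Two-tier contig binner: DBSCAN on GC-log(coverage), DPGMM on TNF.

    Operates on a feature table (see
    :func:`duobin.features.build_feature_table`): the first tier clusters
    contigs by abundance and GC, the second splits each coarse bin on
    tetranucleotide composition, and bins smaller than ``min_bin_size`` are
    dissolved.

    Attributes
    ----------
    labels_ : ndarray
        Final bin per contig (UNCLASSIFIED = -1 for noise/dissolved).
    primary_labels_ : ndarray
        First-tier DBSCAN labels.
    assignment_ : Series
        ``labels_`` indexed by contig id.
    n_bins_ : int
    """

    def __init__(
        self,
        epsilon: float | None = None,
        min_points: int = DEFAULT_MIN_POINTS,
        variance_threshold: float = 0.90,
        n_iterations: int = 300,
        burn_in: int = 100,
        min_bin_size: int = 5,
        covariance: str = "auto",
        alpha: float | None = None,
        max_components_init: int = 20,
        random_state: int = 0,
    ):
        self.epsilon = epsilon
        self.min_points = min_points
        self.variance_threshold = variance_threshold
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.min_bin_size = min_bin_size
        self.covariance = covariance
        self.alpha = alpha
        self.max_components_init = max_components_init
        self.random_state = random_state

    def _refinement_config(self) -> RefinementConfig:
        return RefinementConfig(
            variance_threshold=self.variance_threshold,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            min_bin_size=self.min_bin_size,
            covariance=self.covariance,
            alpha=self.alpha,
            max_components_init=self.max_components_init,
            seed=int(self.random_state),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "CoverageCompositionBinner":
        """Bin the contigs of a feature table.

        Parameters
        ----------
        X : DataFrame
            Feature table with ``gc``, ``log_coverage`` and the 136 canonical
            tetramer columns, indexed by contig id.
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "CoverageCompositionBinner expects the feature table "
                "DataFrame produced by build_feature_table"
            )
        primary = primary_bin(X, epsilon=self.epsilon, min_points=self.min_points)
        final = refine_bins(primary, X, self._refinement_config())
        self.primary_labels_ = primary.to_numpy()
        self.assignment_ = final
        self.labels_ = final.to_numpy()
        self.n_bins_ = int(final.max() + 1) if (final >= 0).any() else 0
        return self


def run_pipeline(
    contigs_path: str | os.PathLike,
    coverage_path: str | os.PathLike,
    config: RunConfig,
) -> dict:
    """Run the full workflow on files and write all outputs.

    Writes ``bin_NNN.fasta`` files, ``unclassified.fasta``,
    ``assignments.tsv`` (covering every input contig, with filtered contigs
    marked unclassified), ``features.tsv`` and ``summary.json``. Returns the
    summary dict. Any stage failure raises :class:`PipelineStageError`
    naming the stage.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineStageError(name, exc) from exc

    contigs = stage("read_contigs", io.read_contigs, contigs_path)
    coverages = stage("read_coverage", io.read_coverage, coverage_path)
    features = stage(
        "build_features", build_feature_table, contigs, coverages,
        config.min_length,
    )
    exclusions = features.attrs["exclusions"]

    binner = CoverageCompositionBinner(
        epsilon=config.epsilon,
        min_points=config.min_points,
        variance_threshold=config.refinement.variance_threshold,
        n_iterations=config.refinement.n_iterations,
        burn_in=config.refinement.burn_in,
        min_bin_size=config.refinement.min_bin_size,
        covariance=config.refinement.covariance,
        alpha=config.refinement.alpha,
        max_components_init=config.refinement.max_components_init,
        random_state=config.seed,
    )
    stage("binning", binner.fit, features)

    # extend the assignment to every input contig (filtered ones unclassified)
    full = pd.Series(
        UNCLASSIFIED, index=pd.Index([c.id for c in contigs], name="id"),
        dtype=int, name="bin",
    )
    full.loc[binner.assignment_.index] = binner.assignment_

    outdir = Path(config.outdir)
    stage("write_outputs", outdir.mkdir, parents=True, exist_ok=True)
    stage("write_outputs", io.write_feature_table, features, outdir / "features.tsv")
    stage("write_outputs", io.write_assignments, full, outdir / "assignments.tsv")
    stage("write_outputs", io.write_bins, contigs, full, outdir)

    n_noise = int(
        (binner.assignment_ == UNCLASSIFIED).sum()
    )
    bin_sizes = (
        binner.assignment_[binner.assignment_ >= 0].value_counts().sort_index()
    )
    summary = {
        "parameters": {
            "min_length": config.min_length,
            "epsilon": config.epsilon,
            "min_points": config.min_points,
            "refinement": dataclasses.asdict(config.refinement),
            "seed": config.seed,
        },
        "counts": {
            "input_contigs": exclusions["input"],
            "too_short": exclusions["too_short"],
            "zero_coverage": exclusions["zero_coverage"],
            "evaluated": exclusions["retained"],
            "classified": int((full >= 0).sum()),
            "unclassified": int((full == UNCLASSIFIED).sum()),
        },
        "n_bins": binner.n_bins_,
        "bin_sizes": {int(k): int(v) for k, v in bin_sizes.items()},
    }
    assert (
        summary["counts"]["classified"] + summary["counts"]["unclassified"]
        == summary["counts"]["input_contigs"]
    ), "contig conservation violated"
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info(
        "binned %d contigs into %d bins (%d unclassified)",
        summary["counts"]["classified"],
        summary["n_bins"],
        summary["counts"]["unclassified"],
    )
    return summary
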