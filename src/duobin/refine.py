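"""Second-tier refinement: split each primary bin in tetranucleotide space.

A primary (GC-coverage) bin can still mix species whose abundances coincide.
Each sufficiently large bin is therefore re-clustered on composition alone:
the 136-dimensional tetranucleotide profiles of its contigs are reduced by
PCA and the scores clustered with a Dirichlet-process Gaussian mixture
(collapsed Gibbs), which decides the number of sub-bins from the data.
Refinement only ever splits — contigs from different primary bins never end
up together — and sub-bins smaller than ``min_bin_size`` are dissolved to
UNCLASSIFIED, trading recall for precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import tnf_matrix
from .io import UNCLASSIFIED
from .mixture import DirichletProcessGMM

logger = logging.getLogger(__name__)

#: hard cap on retained principal components
MAX_COMPONENTS = 10


@dataclass
class RefinementConfig:
    """Settings for the PCA + DPGMM refinement stage.

    variance_threshold
        Keep the smallest number of principal components whose cumulative
        explained variance reaches this fraction (capped at 10).
    n_iterations / burn_in
        Gibbs sweeps in total / discarded before the posterior is tracked.
    seed
        Governs all sampler randomness; per-bin streams are derived from it.
    min_bin_size
        Output bins with fewer contigs are dissolved to UNCLASSIFIED; bins
        smaller than twice this are not split at all (refining a handful of
        points is statistically meaningless).
    alpha
        DP concentration; None resamples it under a Gamma(1,1) prior.
    """

    variance_threshold: float = 0.90
    max_components_init: int = 20
    n_iterations: int = 300
    burn_in: int = 100
    seed: int = 0
    min_bin_size: int = 5
    covariance: str = "auto"
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.variance_threshold <= 1):
            raise ValueError("variance_threshold must be in (0, 1]")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.min_bin_size < 1:
            raise ValueError("min_bin_size must be >= 1")


def pca_reduce(
    profiles: np.ndarray, variance_threshold: float = 0.90
) -> np.ndarray | None:
    """Project profiles onto their leading principal components.

    Keeps the smallest number of components whose cumulative explained
    variance reaches ``variance_threshold``, capped at
    ``min(10, n-1, n_features)``. Returns the score matrix in
    decreasing-variance order, or None when the input is degenerate (fewer
    than two rows, or zero total variance) — the caller then passes the bin
    through unrefined.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        return None
    n, p = X.shape
    cap = min(MAX_COMPONENTS, n - 1, p)
    centered = X - X.mean(axis=0)
    scale = max(np.abs(X).max(), 1.0)
    if np.allclose(centered, 0.0, atol=1e-12 * scale):
        return None  # all rows identical

    pca = PCA(n_components=cap, svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    d = min(d, cap)
    return scores[:, :d]


def _bin_seed(seed: int, bin_label: int) -> int:
    """Deterministic per-bin sampler seed derived from the run seed."""
    ss = np.random.SeedSequence([seed, bin_label])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def refine_bins(
    primary: pd.Series,
    features: pd.DataFrame,
    config: RefinementConfig | None = None,
) -> pd.Series:
    """Split primary bins by composition and filter small output bins.

    Each primary bin with at least ``2 * min_bin_size`` contigs is split via
    ``pca_reduce`` -> DPGMM; smaller bins pass through unsplit. All resulting
    bins below ``min_bin_size`` are then dissolved to UNCLASSIFIED. Final
    labels are contiguous integers; primary-step noise stays UNCLASSIFIED.

    Parameters
    ----------
    primary : Series
        Primary bin label per contig id (UNCLASSIFIED for noise).
    features : DataFrame
        Feature table covering the same contigs (tetranucleotide columns are
        used).
    """
    if config is None:
        config = RefinementConfig()
    if not primary.index.equals(features.index):
        primary = primary.reindex(features.index)
        if primary.isna().any():
            raise ValueError("primary assignment does not cover all contigs")
        primary = primary.astype(int)

    groups: list[pd.Index] = []  # candidate final bins, deterministic order
    for label in sorted(set(primary) - {UNCLASSIFIED}):
        ids = primary.index[primary == label]
        if len(ids) >= 2 * config.min_bin_size:
            reduced = pca_reduce(
                tnf_matrix(features.loc[ids]), config.variance_threshold
            )
            if reduced is None:
                sub = np.zeros(len(ids), dtype=int)
            else:
                model = DirichletProcessGMM(
                    n_iterations=config.n_iterations,
                    burn_in=config.burn_in,
                    alpha=config.alpha,
                    covariance=config.covariance,
                    max_components_init=config.max_components_init,
                    random_state=_bin_seed(config.seed, int(label)),
                )
                sub = model.fit(reduced).labels_
            for s in range(sub.max() + 1):
                groups.append(ids[sub == s])
        else:
            groups.append(ids)

    final = pd.Series(UNCLASSIFIED, index=features.index, name="bin", dtype=int)
    next_label = 0
    dissolved = 0
    for ids in groups:
        if len(ids) < config.min_bin_size:
            dissolved += len(ids)
            continue
        final.loc[ids] = next_label
        next_label += 1
    if dissolved:
        logger.info(
            "refinement dissolved %d contigs in bins smaller than %d",
            dissolved,
            config.min_bin_size,
        )
    return final
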