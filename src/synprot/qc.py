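"""Principal-component QC of the normalized protein table.

Samples are projected onto principal components of the protein intensity
matrix (centered, not scaled — the default of the usual PCA routines) to
verify within-group similarity and between-group separation across the
treatment conditions.  Proteins with any missing value are excluded
(complete-case restriction) and the count is logged.  Component signs are
fixed deterministically — the largest-magnitude loading of each component
is made positive — so outputs are reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ProteinQuantTable

__all__ = ["PcaResult", "pca_samples", "pca_coordinates_table"]

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Sample coordinates, explained-variance fractions and loadings."""

    coordinates: pd.DataFrame        # samples x components
    variance_explained: np.ndarray   # fraction per component, nonincreasing
    loadings: pd.DataFrame           # proteins x components
    n_proteins_used: int
    n_proteins_dropped: int


def pca_samples(table: ProteinQuantTable, n_components: int | None = 3) -> PcaResult:
    """PCA of samples over complete-case proteins.

    ``n_components=None`` keeps every component (up to min(n_samples,
    n_proteins)), which makes the centered data exactly reconstructable as
    ``coordinates @ loadings.T``.
    """
    X_df = table.intensities
    n_samples = X_df.shape[1]
    if n_samples < 2:
        raise ValueError(f"PCA needs at least 2 samples, got {n_samples}")
    complete = X_df.dropna(axis=0)
    dropped = X_df.shape[0] - complete.shape[0]
    if dropped:
        logger.info("PCA complete-case restriction: dropped %d/%d proteins with "
                    "missing values", dropped, X_df.shape[0])
    if complete.shape[0] == 0:
        raise ValueError("no complete-case proteins available for PCA")

    X = complete.to_numpy(dtype=float).T  # samples x proteins
    max_comp = min(X.shape)
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    load = pca.components_.T  # proteins x components

    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k):
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1.0
            coords[:, c] *= -1.0

    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=X_df.columns, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(load, index=complete.index, columns=comp_names),
        n_proteins_used=complete.shape[0],
        n_proteins_dropped=dropped,
    )


def pca_coordinates_table(result: PcaResult, table: ProteinQuantTable,
                          n_components: int = 3) -> pd.DataFrame:
    """Samples x (PC1..PCk, condition, batch) table for a 3-D plot."""
    cols = [f"PC{i + 1}" for i in range(min(n_components, result.coordinates.shape[1]))]
    out = result.coordinates[cols].copy()
    if table.condition is not None:
        out["condition"] = table.condition.loc[out.index]
        out["batch"] = table.batch.loc[out.index]
    out.index.name = "sample"
    return out
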