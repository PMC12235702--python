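"""Gene-set enrichment: hypergeometric over-representation and preranked GSEA.

Over-representation analysis (ORA) tests whether a query gene list (e.g. the
down-regulated proteins of a contrast) overlaps a gene set more than chance
given a background universe, with a one-sided upper-tail hypergeometric
p-value and Benjamini-Hochberg q-values; a set is significant at nominal
p < 0.05.

Preranked GSEA walks a weighted Kolmogorov-Smirnov running sum down a ranked
gene list: the sum increments by ``|score|^w / sum_hits |score|^w`` at set
members and decrements by ``1/(N - Nh)`` elsewhere; the enrichment score
(ES) is the signed extremum.  Significance comes from a gene-label
permutation null: the nominal p-value is one-sided among same-sign
permutation scores (with an add-one pseudocount so p is never 0), the
normalized enrichment score (NES) divides ES by the mean same-sign
permutation |ES|, and FDR q-values follow the standard NES-pooling
procedure.  A set is significant when FDR < 0.25 and nominal p < 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "OraResult",
    "GseaResult",
    "ora_hypergeometric",
    "gsea_enrichment_score",
    "gsea_significance",
]

logger = logging.getLogger(__name__)


@dataclass
class OraResult:
    """Per-set over-representation statistics.

    ``table`` columns: name, size_in_universe, query_size, overlap,
    expected_overlap, odds_ratio, nominal_p, fdr_q, significant.
    """

    table: pd.DataFrame
    universe_size: int
    p_threshold: float = 0.05


@dataclass
class GseaResult:
    """Per-set preranked GSEA statistics.

    ``table`` columns: name, size, es, nes, nominal_p, fdr_q, significant,
    flag.  ``skipped`` lists sets with no overlap with the ranking or a
    size outside the configured bounds.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None
    weight_exponent: float
    fdr_threshold: float = 0.25
    p_threshold: float = 0.05
    skipped: tuple[str, ...] = ()


def ora_hypergeometric(
    query,
    sets: GeneSetCollection,
    universe,
    p_threshold: float = 0.05,
) -> OraResult:
    """One-sided hypergeometric over-representation test per gene set.

    ``query`` must be a subset of ``universe``; every set is intersected
    with the universe before testing.  The p-value is P[X >= overlap] for
    X hypergeometric(N=|universe|, K=|set|, n=|query|).
    """
    universe = [g.upper() for g in universe]
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if len(uni) != len(universe):
        raise ValueError("duplicate genes in universe")
    query = [g.upper() for g in query]
    qset = set(query)
    if not qset:
        raise ValueError("empty query gene list")
    outside = sorted(qset - uni)
    if outside:
        raise ValueError(f"query genes absent from the universe: {outside[:10]}")

    N, n = len(uni), len(qset)
    rows = []
    for gs in sets:
        members = set(gs.members) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & qset)
        # P[X >= k], upper tail inclusive
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        expected = K * n / N
        # Haldane-corrected odds ratio of the 2x2 overlap table
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append((gs.name, K, n, k, expected, odds, p))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(
        rows,
        columns=["name", "size_in_universe", "query_size", "overlap",
                 "expected_overlap", "odds_ratio", "nominal_p"],
    )
    table["fdr_q"] = multipletests(table["nominal_p"], method="fdr_bh")[1]
    table["significant"] = table["nominal_p"] < p_threshold
    table = table.sort_values("nominal_p", kind="stable").reset_index(drop=True)
    return OraResult(table=table, universe_size=N, p_threshold=p_threshold)


def _running_sum_batch(abs_scores_w: np.ndarray, hit_idx: np.ndarray) -> np.ndarray:
    """Running sums for a batch of hit-position sets.

    ``abs_scores_w`` is |score|^w along the ranking (length N);
    ``hit_idx`` is (B, k) integer positions.  Returns (B, N) running sums.
    """
    B, k = hit_idx.shape
    N = abs_scores_w.shape[0]
    inc = np.full((B, N), -1.0 / (N - k))
    w_vals = abs_scores_w[hit_idx]
    norm = w_vals.sum(axis=1, keepdims=True)
    # all-zero hit weights (can happen with w > 0 and zero scores): fall back
    # to equal weights so the walk remains defined
    zero = norm[:, 0] == 0
    if zero.any():
        w_vals = w_vals.copy()
        w_vals[zero] = 1.0
        norm = w_vals.sum(axis=1, keepdims=True)
    np.put_along_axis(inc, hit_idx, w_vals / norm, axis=1)
    return np.cumsum(inc, axis=1)


def _signed_extremum(running: np.ndarray) -> np.ndarray:
    """ES per row: the running-sum extremum of largest magnitude.

    An exact |max| == |min| tie resolves to the positive extremum.
    """
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def gsea_enrichment_score(
    ranked: pd.DataFrame,
    gene_set,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and running sum of one gene set on a ranked list.

    ``ranked`` has columns ``gene`` (unique) and ``score``, sorted
    descending.  Returns ``(es, running_sum)``.
    """
    genes = ranked["gene"].to_numpy()
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    members = {g.upper() for g in (gene_set.members if hasattr(gene_set, "members") else gene_set)}
    hit_mask = np.isin(genes, list(members))
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if k == len(genes):
        # degenerate: every gene is a hit; the walk is all increments
        scores_w = np.abs(ranked["score"].to_numpy()) ** weight_exponent
        if scores_w.sum() == 0:
            scores_w = np.ones_like(scores_w)
        running = np.cumsum(scores_w / scores_w.sum())
        return 1.0, running
    abs_w = np.abs(ranked["score"].to_numpy(dtype=float)) ** weight_exponent
    hit_idx = np.flatnonzero(hit_mask)[None, :]
    running = _running_sum_batch(abs_w, hit_idx)[0]
    es = float(_signed_extremum(running[None, :])[0])
    return es, running


def _set_null(abs_w: np.ndarray, k: int, n_perm: int, rng: np.random.Generator,
              method: str) -> np.ndarray:
    """Null ES distribution for a set of size k by gene-label permutation."""
    N = abs_w.shape[0]
    if method == "exhaustive":
        combos = np.array(list(itertools.combinations(range(N), k)), dtype=int)
        return _signed_extremum(_running_sum_batch(abs_w, combos))
    idx = np.empty((n_perm, k), dtype=int)
    for b in range(n_perm):
        idx[b] = rng.choice(N, size=k, replace=False)
    return _signed_extremum(_running_sum_batch(abs_w, idx))


def gsea_significance(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    fdr_threshold: float = 0.25,
    p_threshold: float = 0.05,
    permutations: str = "random",
) -> GseaResult:
    """Permutation-based significance for every gene set on one ranking.

    ``permutations="exhaustive"`` enumerates every possible placement of the
    set's labels (only sensible when C(N, k) is small); the default draws
    ``n_perm`` random placements and applies the add-one pseudocount so
    p-values are never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if permutations not in ("random", "exhaustive"):
        raise ValueError(f"unknown permutation scheme {permutations!r}")
    genes = ranked["gene"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    if len(gene_pos) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    N = len(genes)
    abs_w = np.abs(ranked["score"].to_numpy(dtype=float)) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    skipped = []
    null_by_set: dict[str, np.ndarray] = {}
    for gs in sets:
        hit_idx = np.array(sorted(gene_pos[m] for m in gs.members if m in gene_pos))
        k = hit_idx.size
        if k == 0:
            logger.info("skipping set %s: no overlap with the ranked list", gs.name)
            skipped.append(gs.name)
            continue
        if k < min_size or k > max_size or k == N:
            logger.info("skipping set %s: size %d outside [%d, %d]",
                        gs.name, k, min_size, max_size)
            skipped.append(gs.name)
            continue
        es = float(_signed_extremum(_running_sum_batch(abs_w, hit_idx[None, :]))[0])
        null = _set_null(abs_w, k, n_perm, rng, permutations)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        flag = ""
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
            flag = "degenerate_null"
        else:
            extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
            if permutations == "exhaustive":
                p = extreme / n_same
            else:
                p = (1 + extreme) / (1 + n_same)
            denom = float(np.abs(null[same_sign]).mean())
            nes = es / denom if denom > 0 else np.nan
        null_by_set[gs.name] = null
        rows.append((gs.name, k, es, nes, p, flag))

    if not rows:
        raise ValueError("no gene set eligible for GSEA on this ranking")
    table = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "nominal_p", "flag"])
    table["fdr_q"] = _nes_pooled_fdr(table, null_by_set)
    table["significant"] = (table["fdr_q"] < fdr_threshold) & (table["nominal_p"] < p_threshold)
    table = table[["name", "size", "es", "nes", "nominal_p", "fdr_q", "significant", "flag"]]
    table = table.sort_values("nominal_p", kind="stable").reset_index(drop=True)
    return GseaResult(table=table, n_perm=n_perm, seed=seed,
                      weight_exponent=weight_exponent, fdr_threshold=fdr_threshold,
                      p_threshold=p_threshold, skipped=tuple(skipped))


def _nes_pooled_fdr(table: pd.DataFrame, null_by_set: dict[str, np.ndarray]) -> np.ndarray:
    """FDR q-values by pooling normalized permutation scores across sets.

    Each set's null ES values are normalized by that set's same-sign mean
    |ES| (the same normalization that produced the observed NES); positive
    and negative scores are handled separately.
    """
    pooled = []
    for name, null in null_by_set.items():
        pos = null[null >= 0]
        neg = null[null < 0]
        if pos.size and pos.mean() > 0:
            pooled.append(pos / pos.mean())
        if neg.size:
            pooled.append(neg / np.abs(neg).mean())
    pooled = np.concatenate(pooled) if pooled else np.array([])
    obs = table["nes"].to_numpy(dtype=float)
    q = np.full(obs.shape, np.nan)
    pos_pool = pooled[pooled >= 0]
    neg_pool = pooled[pooled < 0]
    n_obs_pos = np.sum(obs >= 0)
    n_obs_neg = np.sum(obs < 0)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            num = np.mean(pos_pool >= nes) if pos_pool.size else 0.0
            den = np.sum(table["nes"] >= nes) / n_obs_pos if n_obs_pos else 0.0
        else:
            num = np.mean(neg_pool <= nes) if neg_pool.size else 0.0
            den = np.sum(table["nes"] <= nes) / n_obs_neg if n_obs_neg else 0.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q
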