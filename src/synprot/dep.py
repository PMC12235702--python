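"""Differential expression on TMT protein quantification tables.

For each named contrast (e.g. PS/C within batch 1) the module computes a
per-protein log2 fold change (mean difference of log2 intensities), a
two-sample Student t statistic and two-sided p-value, and applies two
alternative filters for differentially expressed proteins (DEPs):

* the volcano rule: p < 0.05 and |log2FC| > 0.58;
* the SD rule used to pick down-regulated proteins for over-representation
  analysis: p < 0.05 and a log2FC z-score below -1.96 within the contrast.

Proteins with fewer than two quantified values in either group, or with
zero pooled variance and a nonzero mean difference, are flagged rather than
silently dropped.  No multiple-testing correction enters the DEP calls
themselves (the filters act on raw p-values); a Benjamini-Hochberg q-value
column is provided for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuantTable

__all__ = [
    "ComparisonSpec",
    "ComparisonResult",
    "STANDARD_CONTRASTS",
    "log2_transform_and_normalize",
    "compare_groups",
    "filter_deps",
    "filter_sd_down",
    "volcano_table",
]

#: The six contrasts of the two-batch design: numerator, denominator, batch.
STANDARD_CONTRASTS = (
    ("P/C", "P", "CTL", 1),
    ("S/C", "S", "CTL", 1),
    ("PS/C.b1", "PS", "CTL", 1),
    ("PS/C.b2", "PS", "CTL", 2),
    ("PS/P", "PS", "P", 2),
    ("PS/S", "PS", "S", 2),
)


@dataclass(frozen=True)
class ComparisonSpec:
    """One named two-group contrast, optionally scoped to a single batch."""

    name: str
    numerator: str
    denominator: str
    batch: int | None = None

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError(f"{self.name}: numerator equals denominator")


@dataclass
class ComparisonResult:
    """Per-protein statistics for one contrast.

    ``table`` columns: protein_id (index), gene_symbol, log2_fc, t_stat,
    p_value, q_value, n_num, n_den, is_dep, direction, flag.  ``flag`` is
    empty for clean rows, "insufficient_replicates" or "zero_variance"
    otherwise (those rows get p = NaN and are never DEPs).
    """

    spec: ComparisonSpec
    table: pd.DataFrame
    p_threshold: float
    fc_threshold: float

    @property
    def n_dep(self) -> int:
        return int(self.table["is_dep"].sum())


def log2_transform_and_normalize(
    table: ProteinQuantTable, method: str = "median_center"
) -> ProteinQuantTable:
    """Log2-transform reporter intensities; optionally median-center samples.

    ``median_center`` subtracts each sample's median log2 intensity so that
    per-sample medians are 0; ``none`` leaves values untouched beyond the
    log2 transform.  Missing values stay missing.
    """
    if method not in ("median_center", "none"):
        raise ValueError(f"unknown normalization method {method!r}")
    if table.log2_transformed:
        raise ValueError("table is already log2-transformed")
    all_missing = table.intensities.isna().all(axis=0)
    if all_missing.any():
        bad = list(table.intensities.columns[all_missing])
        raise ValueError(f"sample(s) with all-missing intensities: {bad}")
    log2 = np.log2(table.intensities)
    if method == "median_center":
        log2 = log2 - log2.median(axis=0)
    return ProteinQuantTable(
        intensities=log2,
        gene_symbols=table.gene_symbols,
        condition=table.condition,
        batch=table.batch,
        filtered_counts=dict(table.filtered_counts),
        log2_transformed=True,
        normalization=method,
    )


def _student_t(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised two-sample pooled-variance (Student) t-test, two-sided.

    Rows are proteins.  Returns (t, p, n1, n2, flag) where flag marks
    degenerate rows: insufficient replicates or zero pooled variance with a
    nonzero mean difference.  The 0/0 case (identical groups with zero
    spread) is defined as t = 0, p = 1.
    """
    n1 = np.sum(~np.isnan(num), axis=1)
    n2 = np.sum(~np.isnan(den), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / df<=0 slices
        m1 = np.nanmean(num, axis=1)
        m2 = np.nanmean(den, axis=1)
        v1 = np.nanvar(num, axis=1, ddof=1)
        v2 = np.nanvar(den, axis=1, ddof=1)
    diff = m1 - m2
    df = n1 + n2 - 2
    enough = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = diff / se
    zero_var = enough & (se == 0)
    t = np.where(zero_var & (diff == 0), 0.0, t)
    p = np.full(t.shape, np.nan)
    ok = enough & np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    flag = np.full(t.shape, "", dtype=object)
    flag[~enough] = "insufficient_replicates"
    flag[zero_var & (diff != 0)] = "zero_variance"
    t[~ok] = np.nan
    return t, p, n1, n2, diff, flag


def _welch_t(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, ...]:
    n1 = np.sum(~np.isnan(num), axis=1)
    n2 = np.sum(~np.isnan(den), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(num, axis=1), np.nanmean(den, axis=1)
        v1 = np.nanvar(num, axis=1, ddof=1)
        v2 = np.nanvar(den, axis=1, ddof=1)
    diff = m1 - m2
    enough = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    zero_var = enough & (se2 == 0)
    t = np.where(zero_var & (diff == 0), 0.0, t)
    df = np.where(zero_var, n1 + n2 - 2, df)
    p = np.full(t.shape, np.nan)
    ok = enough & np.isfinite(t) & np.isfinite(df)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    flag = np.full(t.shape, "", dtype=object)
    flag[~enough] = "insufficient_replicates"
    flag[zero_var & (diff != 0)] = "zero_variance"
    t[~ok & ~(zero_var & (diff == 0))] = np.nan
    return t, p, n1, n2, diff, flag


def compare_groups(
    table: ProteinQuantTable,
    spec: ComparisonSpec,
    p_threshold: float = 0.05,
    fc_threshold: float = 0.58,
    test: str = "student",
) -> ComparisonResult:
    """Two-group differential expression for one contrast.

    The table must be log2-transformed with a design attached.  log2_fc is
    the numerator-minus-denominator mean difference on the log2 scale
    (equivalently log2 of the ratio of geometric group means on the linear
    scale).  ``is_dep`` is True iff p < ``p_threshold`` and |log2_fc| >
    ``fc_threshold``.
    """
    if not table.log2_transformed:
        raise ValueError("compare_groups expects a log2-transformed table "
                         "(run log2_transform_and_normalize first)")
    if table.condition is None:
        raise ValueError("no design attached; call with_design() first")
    num_samples = table.samples_for(spec.numerator, spec.batch)
    den_samples = table.samples_for(spec.denominator, spec.batch)
    scope = f" in batch {spec.batch}" if spec.batch is not None else ""
    if not num_samples:
        raise ValueError(f"contrast {spec.name}: no samples for condition "
                         f"{spec.numerator!r}{scope}")
    if not den_samples:
        raise ValueError(f"contrast {spec.name}: no samples for condition "
                         f"{spec.denominator!r}{scope}")

    num = table.intensities[num_samples].to_numpy(dtype=float)
    den = table.intensities[den_samples].to_numpy(dtype=float)
    if test == "student":
        t, p, n1, n2, log2_fc, flag = _student_t(num, den)
    elif test == "welch":
        t, p, n1, n2, log2_fc, flag = _welch_t(num, den)
    else:
        raise ValueError(f"unknown test {test!r}; use 'student' or 'welch'")

    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    is_dep = ok & (p < p_threshold) & (np.abs(log2_fc) > fc_threshold) & (flag == "")
    direction = np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "none"))
    out = pd.DataFrame(
        {
            "gene_symbol": table.gene_symbols.to_numpy(),
            "log2_fc": log2_fc,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "n_num": n1,
            "n_den": n2,
            "is_dep": is_dep,
            "direction": direction,
            "flag": flag,
        },
        index=table.intensities.index,
    )
    return ComparisonResult(spec=spec, table=out, p_threshold=p_threshold,
                            fc_threshold=fc_threshold)


def filter_deps(result: ComparisonResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the DEPs of a contrast into up- and down-regulated subsets."""
    deps = result.table[result.table["is_dep"]]
    up = deps[deps["log2_fc"] > 0]
    down = deps[deps["log2_fc"] < 0]
    return up, down


def filter_sd_down(result: ComparisonResult, sd_multiplier: float = 1.96,
                   p_threshold: float = 0.05) -> pd.DataFrame:
    """Down-regulated subset by the SD rule (input list for ORA).

    Selects proteins with p < ``p_threshold`` whose log2 fold change lies
    more than ``sd_multiplier`` standard deviations below the contrast's
    mean log2 fold change.
    """
    fc = result.table["log2_fc"]
    finite = fc[np.isfinite(fc)]
    if len(finite) < 2:
        raise ValueError("need at least two finite log2 fold changes to estimate the SD")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation of log2 fold changes; SD rule undefined")
    z = (fc - finite.mean()) / sd
    mask = (result.table["p_value"] < p_threshold) & (z < -sd_multiplier)
    mask &= result.table["flag"] == ""
    out = result.table[mask.fillna(False)].copy()
    out["fc_z_score"] = z[mask.fillna(False)]
    return out


def volcano_table(result: ComparisonResult) -> pd.DataFrame:
    """Volcano-plot export: log2_fc on x, -log10 p on y, DEP flag.

    p = 0 cannot arise from the t distribution but is guarded by flooring
    at the smallest positive normal float (and flagged).
    """
    tbl = result.table
    p = tbl["p_value"].to_numpy(dtype=float)
    floored = p == 0
    p_safe = np.where(floored, np.finfo(float).tiny, p)
    with np.errstate(invalid="ignore"):
        y = -np.log10(p_safe)
    flag = tbl["flag"].to_numpy(dtype=object).copy()
    flag[floored] = np.where(flag[floored] == "", "p_floored",
                             flag[floored] + ";p_floored")
    return pd.DataFrame(
        {
            "gene_symbol": tbl["gene_symbol"],
            "log2_fc": tbl["log2_fc"],
            "neg_log10_p": y,
            "is_dep": tbl["is_dep"],
            "direction": tbl["direction"],
            "flag": flag,
        },
        index=tbl.index,
    )
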