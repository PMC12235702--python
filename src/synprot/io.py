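"""Readers and writers for the table formats the pipeline touches.

Covers MaxQuant-style proteinGroups tables (tab-separated, with reporter-ion
intensity columns and ``+``-marked reverse/contaminant rows), sample-design
tables mapping TMT channels to condition and batch, GMT gene-set collections
and RNK ranked lists, plus the CSV writers used for every result table.

Conventions follow common Perseus-style preprocessing: rows flagged in any
of the marker columns are dropped (and counted), and zero reporter
intensities are treated as missing values.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "ProteinQuantTable",
    "GeneSet",
    "GeneSetCollection",
    "read_protein_groups",
    "write_protein_groups",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "write_result_csv",
    "CONDITIONS",
    "MARKER_COLUMNS",
    "DEFAULT_INTENSITY_PREFIX",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("CTL", "P", "S", "PS")
MARKER_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")
DEFAULT_INTENSITY_PREFIX = "Reporter intensity corrected"


@dataclass
class ProteinQuantTable:
    """Protein groups x samples intensity matrix with sample annotations.

    ``intensities`` is indexed by protein-group id with one column per
    sample; missing values are NaN.  ``condition`` and ``batch`` are
    per-sample Series (set via :meth:`with_design`).  ``log2_transformed``
    records whether the values are on the log2 scale.
    """

    intensities: pd.DataFrame
    gene_symbols: pd.Series
    condition: pd.Series | None = None
    batch: pd.Series | None = None
    filtered_counts: dict = field(default_factory=dict)
    log2_transformed: bool = False
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicated protein group id after filtering: {dup!r}")
        if not self.log2_transformed:
            vals = self.intensities.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("linear-scale reporter intensities must be nonnegative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    def with_design(self, design: pd.DataFrame) -> "ProteinQuantTable":
        """Attach condition/batch annotations from a design table.

        Every sample in the intensity matrix must appear in the design.
        """
        missing = [s for s in self.sample_names if s not in design.index]
        if missing:
            raise ValueError(
                f"samples present in quant table but absent from design: {missing}"
            )
        design = design.loc[self.sample_names]
        return ProteinQuantTable(
            intensities=self.intensities,
            gene_symbols=self.gene_symbols,
            condition=design["condition"].copy(),
            batch=design["batch"].copy(),
            filtered_counts=dict(self.filtered_counts),
            log2_transformed=self.log2_transformed,
            normalization=self.normalization,
        )

    def samples_for(self, condition: str, batch=None) -> list[str]:
        """Sample names for one condition, optionally restricted to a batch."""
        if self.condition is None:
            raise ValueError("no design attached; call with_design() first")
        mask = self.condition == condition
        if batch is not None:
            mask &= self.batch == batch
        return list(self.condition.index[mask])


def read_protein_groups(
    path,
    intensity_column_prefix: str = DEFAULT_INTENSITY_PREFIX,
    id_column: str = "Protein IDs",
    gene_column: str = "Gene names",
) -> ProteinQuantTable:
    """Read a MaxQuant-style proteinGroups.txt table.

    Rows flagged ``+`` in any present marker column (Reverse, Potential
    contaminant, Only identified by site) are removed and counted in
    ``filtered_counts``.  Zero intensities become missing (NaN).  Intensity
    columns are those starting with ``intensity_column_prefix`` followed by
    a space and a channel/sample label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}; headers: {list(df.columns)}")
    prefix = intensity_column_prefix.rstrip() + " "
    intensity_cols = [c for c in df.columns if c.startswith(prefix)]
    if not intensity_cols:
        raise ValueError(
            f"no intensity columns with prefix {intensity_column_prefix!r} found; "
            f"available headers: {list(df.columns)}"
        )

    filtered_counts: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    for marker in MARKER_COLUMNS:
        if marker in df.columns:
            flagged = df[marker].str.strip() == "+"
            key = marker.lower().replace(" ", "_")
            filtered_counts[key] = int(flagged.sum())
            for line_no in df.index[flagged & keep]:
                logger.info("dropping row %d (%s): flagged %s", line_no + 2,
                            df.loc[line_no, id_column], marker)
            keep &= ~flagged
        else:
            filtered_counts[marker.lower().replace(" ", "_")] = 0
    df = df.loc[keep]

    sample_names = [c[len(prefix):] for c in intensity_cols]
    try:
        mat = df[intensity_cols].replace("", "nan").astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity value: {exc}") from exc
    mat.columns = sample_names
    mat = mat.mask(mat == 0.0)  # zero reporter intensity = missing
    mat.index = df[id_column].to_numpy()
    mat.index.name = "protein_id"

    genes = df[gene_column] if gene_column in df.columns else pd.Series("", index=df.index)
    gene_symbols = pd.Series(genes.str.upper().to_numpy(), index=mat.index, name="gene_symbol")

    return ProteinQuantTable(intensities=mat, gene_symbols=gene_symbols,
                             filtered_counts=filtered_counts)


def write_protein_groups(table: ProteinQuantTable, path,
                         intensity_column_prefix: str = DEFAULT_INTENSITY_PREFIX) -> None:
    """Write a table back to the proteinGroups tab-separated dialect.

    Missing values are written as 0, the dialect's convention.
    """
    if table.log2_transformed:
        raise ValueError("refusing to write log2-transformed values to a linear-scale format")
    out = pd.DataFrame({"Protein IDs": table.protein_ids,
                        "Gene names": table.gene_symbols.to_numpy()})
    for sample in table.sample_names:
        col = table.intensities[sample].fillna(0.0)
        out[f"{intensity_column_prefix} {sample}"] = col.to_numpy()
    out["Reverse"] = ""
    out["Potential contaminant"] = ""
    out.to_csv(path, sep="\t", index=False)


def read_design(path, conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Read a sample-design table with columns sample, condition, batch.

    Returns a DataFrame indexed by sample name.  Conditions are restricted
    to the declared vocabulary (default CTL/P/S/PS); batches are integers.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample", "condition", "batch"}
    if not required.issubset(df.columns):
        raise ValueError(f"design must have columns {sorted(required)}; got {list(df.columns)}")
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample row(s) in design: {sorted(set(dup))}")
    bad = sorted(set(df["condition"]) - set(conditions))
    if bad:
        raise ValueError(f"unknown condition(s) {bad}; vocabulary is {list(conditions)}")
    out = df.set_index("sample")[["condition", "batch"]].copy()
    out["batch"] = out["batch"].astype(int)
    return out


def write_design(design: pd.DataFrame, path) -> None:
    design.reset_index().rename(columns={"index": "sample"}).to_csv(path, index=False)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with an optional explicit universe."""

    sets: dict[str, GeneSet]
    universe: tuple[str, ...] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def restrict_to(self, genes) -> "GeneSetCollection":
        """Intersect every set with the given gene universe."""
        allowed = {g.upper() for g in genes}
        new = {}
        for gs in self:
            members = tuple(m for m in gs.members if m in allowed)
            if members:
                new[gs.name] = GeneSet(gs.name, gs.description, members)
        return GeneSetCollection(new, universe=tuple(sorted(allowed)))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``.

    Gene symbols are uppercased on ingestion.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValueError(f"{path}: line {line_no}: gene set with no members")
            name, description = parts[0], parts[1]
            members = tuple(dict.fromkeys(p.strip().upper() for p in parts[2:] if p.strip()))
            if name in sets:
                raise ValueError(f"{path}: line {line_no}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_rnk(path) -> pd.DataFrame:
    """Read a RNK ranked list (gene TAB score), sorted descending by score.

    Ties keep stable input order.  Returns a DataFrame with columns
    ``gene`` (uppercased) and ``score``.
    """
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {line_no}: expected 'gene<TAB>score'")
            gene, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: non-numeric score {raw!r}") from exc
            rows.append((gene.strip().upper(), score))
    df = pd.DataFrame(rows, columns=["gene", "score"])
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r} in ranked list")
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked[["gene", "score"]].to_csv(path, sep="\t", index=False, header=False)


def write_result_csv(df: pd.DataFrame, path, parameters: dict | None = None,
                     index: bool = False) -> None:
    """Write a result table as CSV with a ``#`` header comment recording the
    pipeline version and the parameters used."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# synprot {__version__}\n")
        for key, value in (parameters or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=index)


def read_gene_list(path) -> list[str]:
    """Plain text gene list, one symbol per line (uppercased)."""
    with open(path) as fh:
        return [ln.strip().upper() for ln in fh if ln.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
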