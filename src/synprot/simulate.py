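"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure of a combination-therapy
study on a neuroblastoma cell line, so the whole pipeline can be exercised
and verified without any deposited mass-spectrometry data:

* :func:`synth_dose_response` — a colony-formation-style viability grid:
  single-agent inhibition follows monotone Hill curves along each drug's
  ladder, combination cells follow independent action (the product of the
  single-agent inhibitions over 100) plus an injected true delta surface
  and multiplicative measurement noise.
* :func:`synth_tmt` — an 11-plex-style TMT experiment: log-normal reporter
  intensities with planted per-condition log2 fold changes on a chosen
  fraction of proteins, per-batch offsets, replicate noise and missing
  values, for conditions CTL / P / S / PS across two batches.
* :func:`synth_gene_sets` — gene-set collections in which planted sets are
  drawn preferentially from the planted differential genes (with a
  configurable enrichment odds), and decoy sets uniformly.

Every generator is a pure function of its configuration (seed included):
the same config reproduces identical data, and the ground truth is always
returned machine-readably alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS, GeneSet, GeneSetCollection, ProteinQuantTable
from .synergy import DoseResponseMatrix

__all__ = ["SynthConfig", "synth_dose_response", "synth_tmt", "synth_gene_sets"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Dose ladders default to the drug concentrations used in the long-term
    combination assays (sirolimus-like drug S: 0-40 µM; pyrvinium-like drug
    P: 0-10 µM).  The TMT block defaults to two batches of CTL/P/S/PS in
    triplicate with a planted log2 fold change of 1 on 5% of proteins,
    replicate noise of 0.25 on the log2 scale, batch offsets of SD 0.3 and
    5% missing values.
    """

    seed: int
    # dose-response block
    drug_s_concs: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0)
    drug_p_concs: tuple[float, ...] = (0.0, 0.3125, 0.625, 1.25, 2.5, 5.0, 10.0)
    s_ic50: float = 18.0
    s_hill: float = 1.5
    p_ic50: float = 1.2
    p_hill: float = 1.2
    delta_surface: np.ndarray | None = None   # true Δ per cell (pp); zeros if None
    viability_noise_sd: float = 0.05          # multiplicative CV on viability
    # TMT block
    n_proteins: int = 2000
    fraction_dep: float = 0.05
    planted_log2fc: float = 1.0
    batch_offset_sd: float = 0.3
    replicate_noise_sd: float = 0.25
    missing_rate: float = 0.05
    missing_mode: str = "mcar"   # or "intensity": low-abundance values drop out more
    n_replicates: int = 3
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    # gene-set block
    n_sets: int = 50
    set_size: int = 40
    n_planted_sets: int = 5
    signal_strength: float = 20.0             # enrichment odds for planted sets

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("fraction_dep", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.delta_surface is not None:
            d = np.asarray(self.delta_surface, dtype=float)
            if d.shape != (len(self.drug_s_concs), len(self.drug_p_concs)):
                raise ValueError(
                    f"delta_surface shape {d.shape} does not match dose ladders "
                    f"({len(self.drug_s_concs)}, {len(self.drug_p_concs)})"
                )
            self.delta_surface = d

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("delta_surface"), np.ndarray):
            d["delta_surface"] = d["delta_surface"].tolist()
        return d


def _hill_inhibition(conc: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    """Monotone Hill inhibition in percent; 0 at dose 0, -> 100 at high dose."""
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    pos = conc > 0
    out[pos] = 100.0 * conc[pos] ** hill / (ic50**hill + conc[pos] ** hill)
    return out


def synth_dose_response(config: SynthConfig) -> tuple[DoseResponseMatrix, np.ndarray]:
    """Simulate one viability matrix; returns (matrix, true delta surface).

    Margin row/column carry the single-agent Hill responses; interior cells
    are the independent-action product plus the injected true delta.
    Multiplicative noise acts on viability; at ``viability_noise_sd = 0``
    the pipeline recovers the injected delta exactly.
    """
    rng = np.random.default_rng(config.seed)
    s_inh = _hill_inhibition(np.asarray(config.drug_s_concs), config.s_ic50, config.s_hill)
    p_inh = _hill_inhibition(np.asarray(config.drug_p_concs), config.p_ic50, config.p_hill)
    true_delta = (np.zeros((s_inh.size, p_inh.size)) if config.delta_surface is None
                  else np.asarray(config.delta_surface, dtype=float).copy())
    # an interaction needs both drugs present: margin cells carry no true delta
    true_delta[:, 0] = 0.0
    true_delta[0, :] = 0.0

    inhibition = np.outer(s_inh, p_inh) / 100.0 + true_delta
    # margins are the single-agent measurements themselves
    inhibition[:, 0] = s_inh
    inhibition[0, :] = p_inh
    inhibition[0, 0] = 0.0

    viability = 100.0 - inhibition
    if config.viability_noise_sd > 0:
        viability = viability * (1.0 + rng.normal(0.0, config.viability_noise_sd,
                                                  viability.shape))
    drm = DoseResponseMatrix(config.drug_s_concs, config.drug_p_concs, viability,
                             drug_s_name="sirolimus", drug_p_name="pyrvinium")
    return drm, true_delta


def _planted_effects(rng: np.random.Generator, config: SynthConfig) -> pd.DataFrame:
    """Per-protein true log2 effects for conditions P, S, PS.

    A ``fraction_dep`` slice of proteins is planted per treated condition
    (independent draws, random sign, magnitude ``planted_log2fc``).
    """
    n = config.n_proteins
    effects = pd.DataFrame(0.0, index=[f"PROT{i:05d}" for i in range(n)],
                           columns=["P", "S", "PS"])
    for cond in ("P", "S", "PS"):
        n_dep = int(round(config.fraction_dep * n))
        idx = rng.choice(n, size=n_dep, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_dep)
        effects.iloc[idx, effects.columns.get_loc(cond)] = signs * config.planted_log2fc
    return effects


def synth_tmt(config: SynthConfig) -> tuple[ProteinQuantTable, pd.DataFrame]:
    """Simulate a two-batch TMT protein quantification experiment.

    Returns ``(table, truth)``.  The table carries linear-scale reporter
    intensities with a design attached (conditions CTL/P/S/PS x 2 batches x
    ``n_replicates``).  The truth table holds each protein's true log2
    effect per treated condition and per standard contrast.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    protein_ids = [f"PROT{i:05d}" for i in range(n)]
    gene_symbols = pd.Series([f"GENE{i:05d}" for i in range(n)], index=protein_ids,
                             name="gene_symbol")
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    effects = _planted_effects(rng, config)

    samples, conditions, batches = [], [], []
    for batch in (1, 2):
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                samples.append(f"b{batch}_{cond}_{rep}")
                conditions.append(cond)
                batches.append(batch)

    log2 = np.empty((n, len(samples)))
    batch_offset = {b: rng.normal(0.0, config.batch_offset_sd, n) for b in (1, 2)}
    for j, (cond, batch) in enumerate(zip(conditions, batches)):
        mu = baseline + batch_offset[batch]
        if cond != "CTL":
            mu = mu + effects[cond].to_numpy()
        log2[:, j] = mu + rng.normal(0.0, config.replicate_noise_sd, n)

    linear = np.exp2(log2)
    if config.missing_rate > 0:
        if config.missing_mode == "mcar":
            p_miss = np.full(linear.shape, config.missing_rate)
        elif config.missing_mode == "intensity":
            # dropout probability decreasing in abundance rank, mean = missing_rate
            ranks = stats.rankdata(log2, axis=None).reshape(log2.shape)
            pct = (ranks - 0.5) / log2.size
            p_miss = np.clip(config.missing_rate * 2.0 * (1.0 - pct), 0.0, 1.0)
        else:
            raise ValueError(f"unknown missing_mode {config.missing_mode!r}")
        mask = rng.random(linear.shape) < p_miss
        linear[mask] = np.nan

    intensities = pd.DataFrame(linear, index=pd.Index(protein_ids, name="protein_id"),
                               columns=samples)
    design = pd.DataFrame({"condition": conditions, "batch": batches},
                          index=pd.Index(samples, name="sample"))
    table = ProteinQuantTable(intensities=intensities, gene_symbols=gene_symbols
                              ).with_design(design)

    truth = effects.copy()
    truth.index.name = "protein_id"
    truth["gene_symbol"] = gene_symbols.to_numpy()
    # true log2FC per standard contrast
    truth["true_lfc_P/C"] = truth["P"]
    truth["true_lfc_S/C"] = truth["S"]
    truth["true_lfc_PS/C"] = truth["PS"]
    truth["true_lfc_PS/P"] = truth["PS"] - truth["P"]
    truth["true_lfc_PS/S"] = truth["PS"] - truth["S"]
    return table, truth


def synth_gene_sets(config: SynthConfig, truth: pd.DataFrame,
                    contrast: str = "PS/C",
                    direction: str = "down") -> tuple[GeneSetCollection, pd.DataFrame]:
    """Build a gene-set collection with planted enriched sets.

    Planted sets sample their members with odds ``signal_strength`` in
    favour of genes carrying a true effect in ``contrast``; decoy sets
    sample uniformly.  ``direction`` selects which effect genes seed the
    planted sets: ``"down"`` (default) concentrates them at the bottom of a
    fold-change ranking — the down-regulated programmes that both the ORA
    down-list and negative-NES GSEA should rediscover — ``"up"`` at the
    top, ``"both"`` mixes signs (diluting rank enrichment while leaving
    overlap enrichment intact).  Returns ``(collection, set_truth)`` where
    set_truth labels each set planted or decoy.
    """
    rng = np.random.default_rng(config.seed + 1)
    universe = truth["gene_symbol"].to_numpy()
    n_genes = universe.size
    if config.set_size > n_genes:
        raise ValueError(f"set_size {config.set_size} exceeds universe size {n_genes}")
    lfc = truth[f"true_lfc_{contrast}"].to_numpy()
    if direction == "down":
        de_mask = lfc < 0.0
    elif direction == "up":
        de_mask = lfc > 0.0
    elif direction == "both":
        de_mask = lfc != 0.0
    else:
        raise ValueError(f"unknown direction {direction!r}")

    weights = np.ones(n_genes)
    weights[de_mask] = config.signal_strength
    weights = weights / weights.sum()

    sets: dict[str, GeneSet] = {}
    labels = []
    for i in range(config.n_sets):
        planted = i < config.n_planted_sets
        if planted:
            members = rng.choice(n_genes, size=config.set_size, replace=False, p=weights)
            name = f"PLANTED_SET_{i:02d}"
        else:
            members = rng.choice(n_genes, size=config.set_size, replace=False)
            name = f"DECOY_SET_{i:02d}"
        sets[name] = GeneSet(name, "synthetic", tuple(universe[np.sort(members)]))
        labels.append((name, planted))
    set_truth = pd.DataFrame(labels, columns=["name", "planted"])
    return GeneSetCollection(sets, universe=tuple(universe)), set_truth
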