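# synprot

Analysis pipeline for two-drug combination studies that pair a
dose–response synergy screen with TMT isobaric-label quantitative
proteomics — the setting of combination-therapy work on neuroblastoma cell
lines treated with a sirolimus-like and a pyrvinium-like agent alone and
together (conditions CTL, P, S, PS across two TMT batches).

It is a library first (`import synprot`), with an `examples/` directory of
narrative scripts and a thin `synprot` CLI for shell use.

## What it computes

**Delta synergy score.** Viability percentages on a concentration grid are
converted to inhibition, `I = 100 − viability`; the expected combination
inhibition under independent action is the product of the single-agent
inhibitions,

```
E[i,j] = I_s[i] · I_p[j] / 100,      Δ[i,j] = I_obs[i,j] − E[i,j]
```

with Δ > 0 synergy, Δ < 0 antagonism, and |Δ| within an additivity band
(default 5 pp) additive. Classic Bliss on inhibition
(`E = I_s + I_p − I_s·I_p/100`) is available as `mode="bliss"`.

**Differential expression.** MaxQuant-style proteinGroups tables are
filtered (reverse / contaminant / site-only rows removed, zero intensities
treated as missing), log2-transformed and median-centred; each contrast
gets a two-sided Student t-test and a log2 fold change, and DEPs are called
at `p < 0.05` and `|log2FC| > 0.58`. A second, SD-based rule
(`p < 0.05`, fold change < −1.96 SD) selects the down-regulated list for
over-representation analysis.

**Enrichment.** ORA is the upper-tail hypergeometric test with BH
q-values (significant at nominal p < 0.05). Preranked GSEA walks the
weighted running-sum statistic over a fold-change ranking with a
gene-label permutation null (1000 permutations), reporting ES, NES,
nominal p and an NES-pooled FDR q; significant when FDR < 0.25 and
p < 0.05.

**PCA QC** projects samples onto PC1–PC3 (centred, unscaled,
complete-case proteins) with deterministic component signs.

**Synthetic data.** `synprot.simulate` generates dose–response matrices
with an injected true delta surface, two-batch TMT tables with planted
log2 fold changes, batch offsets and missing values, and gene-set
collections with planted enriched sets — each with its ground truth
returned, so every stage's recovery can be measured.

## Worked example

```
$ python examples/synergy_scoring.py
drugs: sirolimus (rows, uM) x pyrvinium (cols, uM)
delta synergy scores (observed - expected inhibition, pp):
      0.0000   0.3125   0.6250   1.2500   2.5000   5.0000   10.0000
0.0      -0.1      0.0      0.0      0.0      0.0      0.0      0.0
10.0      0.0     -0.8      3.8     -2.8      0.0     -1.1      0.1
20.0      0.0      0.3     -0.6     -0.2     24.8     -1.1      0.6
40.0      0.0      1.0      2.1      1.6      0.1     -0.4      0.1

non-additive concentration pairs:
 drug_s_conc  drug_p_conc     delta   label
        20.0          2.5 24.770958 synergy

planted delta was +25.0 at (20 uM, 2.5 uM); recovered +24.8 despite 2% viability noise.
```

The grid shows Δ per concentration pair: cells near 0 are additive (the
combination behaves as the independent-action expectation), and the one
cell above the +5 pp band is flagged synergy — the planted +25 pp
interaction, recovered to within the injected measurement noise.

```
$ python examples/differential_expression.py
PS vs CTL (batch 1), 2000 proteins, 100 DEPs (50 up / 50 down)
planted effects recovered: 94% of 100
false positives among 1900 null proteins: 0.32% (the fold-change filter keeps this far below the 5% p-threshold)
```

Other scripts: `enrichment_analysis.py` (ORA + GSEA rediscover the
planted gene sets on the PS/C ranking), `pca_qc.py` (replicates cluster
by condition and batch), `full_pipeline.py` (everything from one config;
same as `synprot pipeline run --config cfg.yaml --out out/`).

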