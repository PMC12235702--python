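# Methods

`synprot` implements the computational analysis of a two-drug combination
study: synergy scoring of dose–response matrices, differential expression on
two-batch TMT proteomics, downstream enrichment, and PCA sample QC, together
with synthetic-data generators that plant known effects so each stage's
recovery behaviour can be verified quantitatively.

## Delta synergy score

A combination screen measures percent viability on a grid indexed by the
concentration ladders of drug S (rows) and drug P (columns), with the first
row and column at dose 0 carrying the single-agent responses. The score works
on inhibition rates,

    I = 100 − viability,

with no clamping: values outside [0, 100] are measurement noise and
propagate unchanged (conservation `I + viability = 100` holds exactly).
The expected combination inhibition under independent action is, in the
default `product` mode, the product of the single-agent inhibitions,

    E[i, j] = I_s[i] · I_p[j] / 100,

and the delta synergy score is the per-cell difference Δ = I_obs − E.
Positive Δ is synergy, negative Δ antagonism, and |Δ| within a configurable
additivity band (default 5 percentage points; the "near zero" region is not
otherwise defined, and an explicit band makes the three-way classification
total) is called additive.

Two deliberate design points:

* **Margins.** When the single-agent vectors are read off the matrix's own
  zero-dose row/column, the expected inhibition on those margin cells is set
  to the margin's own observed value — a partner at dose 0 contributes no
  expectation, so single-agent measurements are additive by definition and
  the delta surface is zero on the margins. The (0,0) cell keeps the product
  formula (typically 0). Applying the product formula verbatim on the
  margins would instead charge every single-agent response as "synergy"
  against an expectation of ~0, which is not a statement about drug
  interaction. Interior (combination) cells always use the formula verbatim.
* **Alternative expectation.** The product-of-inhibitions expectation
  differs from classic Bliss independence on inhibition,
  `E = I_s + I_p − I_s·I_p/100` (the two agree only at the extremes). The
  product form is the default and the surface all tests target; the Bliss
  form is available as `mode="bliss"` for comparison and is intentionally
  not silently substituted.

Replicate matrices, when supplied, are averaged per cell on the viability
scale before transformation. Numerics: the whole chain is elementwise
IEEE-double arithmetic; recovery of a planted delta through the
viability round trip is exact to ≲1e-12 (bit-exact when the margins are
exactly representable).

## TMT differential expression

Reporter intensities are read from MaxQuant-style proteinGroups tables;
rows flagged reverse / potential contaminant / only-identified-by-site are
dropped and counted, and zero intensities are treated as missing (the usual
Perseus convention). Intensities are log2-transformed and, by default,
median-centred per sample (`none` disables centring; the normalization is
exposed rather than asserted because real pipelines vary).

Each contrast (PS/C, P/C, S/C within a batch; PS/P, PS/S) is a two-sample
Student t-test (pooled variance, two-sided; Welch available) on the log2
values, with `log2_fc` the numerator-minus-denominator mean difference.
Batches are never pooled: the PS/C contrast is computed separately per batch
because TMT batches are confounded with run effects. Proteins with fewer
than two quantified values in a group are flagged `insufficient_replicates`,
and zero-pooled-variance rows with a nonzero difference are flagged
`zero_variance`; flagged rows keep their fold change but get no p-value and
are never DEPs. The degenerate identical-groups case is defined as t = 0,
p = 1. Two DEP filters exist because the study design uses both:

* volcano rule: `p < 0.05` and `|log2FC| > 0.58` (raw p — no multiplicity
  correction enters the call; a BH q-value column is provided for
  reference);
* SD rule (input list for ORA): `p < 0.05` and fold change more than 1.96
  standard deviations below the contrast's mean log2FC.

The two rules are not equivalent and are deliberately kept as separate
operations.

## Enrichment

**ORA** is the one-sided upper-tail hypergeometric test
`P[X ≥ overlap]` of a query list against each set, both intersected with an
explicit universe (here: the genes actually tested in the contrast), with
BH q-values; a set is significant at nominal p < 0.05. The implementation
is `scipy.stats.hypergeom`; tests verify it against exhaustive enumeration
of all query draws at universe sizes ≤ 12.

**Preranked GSEA** walks the weighted Kolmogorov–Smirnov running sum over
the ranking (genes by log2 fold change): increment `|s|^w / Σ_hits |s|^w`
at set members, decrement `1/(N − N_h)` elsewhere; ES is the signed
extremum (exact |max| = |min| ties resolve positive). The weight exponent
defaults to 1 (the common weighted statistic); `w = 0` gives the
analytically tractable unweighted case used in the exactness tests. The
null is gene-label permutation: `n_perm` (default 1000) random placements
of the set's size. Nominal p is one-sided among same-sign permutation
scores with an add-one pseudocount (so p is never 0 and remains a valid
p-value); NES divides ES by the mean same-sign permutation |ES|; FDR
q-values follow the standard NES-pooling procedure with positive and
negative scores handled separately. Significance requires FDR < 0.25 and
nominal p < 0.05. Set-size bounds default to 5–500; rank ties keep stable
input order. For tiny problems an exhaustive mode enumerates every label
placement, which the tests compare against independent enumeration.

## PCA QC

Samples are projected by PCA (centred, not scaled) over complete-case
proteins — rows with any missing value are excluded and counted, since
imputation would manufacture within-group similarity, the very thing the
plot is meant to check. Component signs are fixed by making each
component's largest-magnitude loading positive, so coordinates are
reproducible across runs. The first three components are exported with
condition and batch labels for a 3-D plot.

## Synthetic data: what it emulates, and what it does not

`SynthConfig` holds the study conditions; every generator is a pure
function of the config (seed mandatory), and ground truth is always
returned machine-readably.

* **Dose–response** (`synth_dose_response`): single-agent inhibition
  follows monotone Hill curves along ladders of 0/10/20/40 µM (drug S,
  sirolimus-like; midpoint 18 µM, slope 1.5) and
  0/0.3125/…/10 µM (drug P, pyrvinium-like; midpoint 1.2 µM, slope 1.2) —
  midpoints sit mid-ladder so the grid spans the informative part of both
  curves. Interior cells are the independent-action product plus an
  injected true-delta surface (margins carry no delta: an interaction needs
  both drugs); multiplicative Gaussian noise with CV 5% (typical
  plate-assay variability) acts on viability, so the recovered delta is
  unbiased and converges to the injected truth in the mean.
* **TMT** (`synth_tmt`): log2 intensities = baseline N(20, 2) + condition
  effect + batch offset N(0, 0.3) + replicate noise N(0, 0.25), then
  exponentiated to the linear reporter scale with 5% values missing
  completely at random. Conditions CTL/P/S/PS in triplicate per batch,
  two batches. 5% of proteins per treated condition carry a planted
  log2FC of ±1. Zero-noise configs recover the planted fold change
  exactly.
* **Gene sets** (`synth_gene_sets`): planted sets sample members with
  configurable odds (default 20:1) in favour of the contrast's true-effect
  genes — by default the down-regulated ones, so planted sets concentrate
  at the bottom of a fold-change ranking and inside the ORA down-list;
  decoy sets sample uniformly.

Missingness is independent of abundance by default (`missing_mode="mcar"`);
an intensity-dependent mode (`"intensity"`, dropout probability decreasing
with abundance rank at the same mean rate) is available for sensitivity
checks. What the generators do **not** emulate: reporter-ion ratio
compression from co-isolation, correlated
protein modules, peptide-to-protein rollup, and curvature/potency shifts
in the dose–response (the injected delta is an additive surface, not a
potency model). Passing tests therefore demonstrate correctness of the
statistical machinery under a clean generative model, not robustness to
every artefact of real mass-spectrometry data.

## Pipeline and reproducibility

`run_all` drives simulate/load → synergy → PCA → six contrasts → ORA →
GSEA from one config whose keys default to the study's printed thresholds
(0.05, 0.58, 1.96, 0.25, 1000 permutations, band 5). Every output
directory gets exactly one `run_manifest.json` recording version, config
echo, SHA-256 of each input, per-stage counts and all seeds (per-contrast
GSEA seeds are derived deterministically from the root seed). Reruns with
the same config are byte-identical for all outputs except the manifest
(wall-clock timestamp) and the log. Default problem sizes in the test and
acceptance runs (≈600–2000 proteins, 10–50 sets, 200–1000 permutations)
were chosen so the planted effects are measured with comfortable
Monte-Carlo margins at desk scale.

## Known limitations

* The product-of-inhibitions expectation is kept verbatim as the default
  even where classic Bliss would differ; users comparing against other
  synergy software should use `mode="bliss"` consciously.
* No moderated (limma-style) variance shrinkage: at n = 3 per group the
  per-protein variance estimate is noisy, and the t-test is exactly what
  it claims, no more.
* ORA reimplements the plain hypergeometric test, not any annotation
  database or EASE-adjusted score; results on real data depend on the GMT
  supplied.
* GSEA uses gene-label permutation only; phenotype permutation is out of
  scope.
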