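"""Delta synergy scoring on drug-combination dose-response matrices.

The workflow mirrors how combination screens are scored in practice: percent
viability measured on a grid of concentrations of two drugs is converted to
inhibition (``100 - viability``), an expected inhibition under independent
action is computed from the single-agent margins, and the delta score is the
observed-minus-expected difference.  Positive delta indicates synergy,
negative delta antagonism, and values inside a configurable band around zero
are called additive.

Two expectation modes are available:

``product`` (default)
    the product of the single-agent inhibitions, ``ZIP[i, j] =
    I_s[i] * I_p[j] / 100`` — independent action expressed as a product of
    inhibition rates.
``bliss``
    classic Bliss independence on inhibition, ``E = I_s + I_p -
    I_s * I_p / 100``.

When the single-agent margins are taken from the matrix's own zero-dose
row/column, the expected inhibition on those margin cells is the margin's
own observed single-agent inhibition (a partner at dose zero contributes no
expectation), and the zero-zero cell follows the mode's formula (typically
zero).  Interior combination cells always use the mode's formula verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseMatrix",
    "SynergyResult",
    "viability_to_inhibition",
    "expected_inhibition",
    "delta_scores",
    "classify_interaction",
    "run_synergy",
    "average_replicates",
    "read_dose_response_csv",
    "write_synergy_tables",
    "plot_delta_heatmap",
]

LABEL_SYNERGY = "synergy"
LABEL_ADDITIVE = "additive"
LABEL_ANTAGONISM = "antagonism"


@dataclass(frozen=True)
class DoseResponseMatrix:
    """Viability grid indexed by two drugs' concentration ladders.

    Rows follow ``drug_s_concs`` (micromolar, strictly increasing, first
    entry may be 0 = the zero-dose margin); columns follow ``drug_p_concs``.
    Viability is in percent; values outside [0, 100] are measurement noise
    and are preserved.
    """

    drug_s_concs: tuple[float, ...]
    drug_p_concs: tuple[float, ...]
    viability: np.ndarray
    drug_s_name: str = "drug_S"
    drug_p_name: str = "drug_P"

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_s_concs", tuple(float(c) for c in self.drug_s_concs))
        object.__setattr__(self, "drug_p_concs", tuple(float(c) for c in self.drug_p_concs))
        v = np.asarray(self.viability, dtype=float)
        object.__setattr__(self, "viability", v)
        if v.shape != (len(self.drug_s_concs), len(self.drug_p_concs)):
            raise ValueError(
                f"viability shape {v.shape} does not match ladders "
                f"({len(self.drug_s_concs)}, {len(self.drug_p_concs)})"
            )
        for name, ladder in (("drug_s_concs", self.drug_s_concs), ("drug_p_concs", self.drug_p_concs)):
            if np.any(np.diff(ladder) <= 0):
                raise ValueError(f"{name} must be strictly increasing, got {ladder}")
        if not np.all(np.isfinite(v)):
            i, j = (int(x) for x in np.argwhere(~np.isfinite(v))[0])
            raise ValueError(f"non-finite viability at cell ({i}, {j}) "
                             f"(S={self.drug_s_concs[i]}, P={self.drug_p_concs[j]})")

    @property
    def has_zero_dose_margins(self) -> bool:
        return self.drug_s_concs[0] == 0.0 and self.drug_p_concs[0] == 0.0


@dataclass(frozen=True)
class SynergyResult:
    """Observed/expected inhibition, delta scores and per-cell labels."""

    dose_response: DoseResponseMatrix
    observed_inhibition: np.ndarray
    expected_inhibition: np.ndarray
    delta: np.ndarray
    labels: np.ndarray
    additivity_band: float
    mode: str = "product"

    def to_long_table(self) -> pd.DataFrame:
        """Long format (one row per concentration pair), heatmap-ready."""
        drm = self.dose_response
        s_idx, p_idx = np.meshgrid(
            np.arange(len(drm.drug_s_concs)), np.arange(len(drm.drug_p_concs)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "drug_s_conc": np.asarray(drm.drug_s_concs)[s_idx.ravel()],
                "drug_p_conc": np.asarray(drm.drug_p_concs)[p_idx.ravel()],
                "observed_inhibition": self.observed_inhibition.ravel(),
                "expected_inhibition": self.expected_inhibition.ravel(),
                "delta": self.delta.ravel(),
                "label": self.labels.ravel(),
            }
        )

    def delta_frame(self) -> pd.DataFrame:
        drm = self.dose_response
        return pd.DataFrame(self.delta, index=list(drm.drug_s_concs), columns=list(drm.drug_p_concs))


def viability_to_inhibition(viability: np.ndarray) -> np.ndarray:
    """Inhibition = 100 - viability, elementwise, with no clamping."""
    v = np.asarray(viability, dtype=float)
    if not np.all(np.isfinite(v)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(v))[0])
        raise ValueError(f"non-finite viability at cell {idx}")
    return 100.0 - v


def expected_inhibition(
    single_agent_s: np.ndarray, single_agent_p: np.ndarray, mode: str = "product"
) -> np.ndarray:
    """Expected combination inhibition under independent action.

    Parameters
    ----------
    single_agent_s, single_agent_p
        Inhibition margins (percent) of each drug alone along its ladder.
    mode
        ``"product"``: product of inhibitions, ``I_s * I_p / 100``.
        ``"bliss"``: ``I_s + I_p - I_s * I_p / 100``.
    """
    s = np.asarray(single_agent_s, dtype=float)
    p = np.asarray(single_agent_p, dtype=float)
    if s.ndim != 1 or p.ndim != 1:
        raise ValueError("single-agent margins must be 1-D vectors")
    prod = np.outer(s, p) / 100.0
    if mode == "product":
        return prod
    if mode == "bliss":
        return s[:, None] + p[None, :] - prod
    raise ValueError(f"unknown expectation mode {mode!r}; use 'product' or 'bliss'")


def delta_scores(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Delta = observed - expected inhibition, elementwise, no rounding."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError(f"shape mismatch: observed {obs.shape} vs expected {exp.shape}")
    return obs - exp


def classify_interaction(delta: np.ndarray, additivity_band: float = 5.0) -> np.ndarray:
    """Label each cell synergy / additive / antagonism.

    Delta above the band is synergy, below the negated band antagonism,
    otherwise additive ("near zero").
    """
    if additivity_band < 0:
        raise ValueError(f"additivity_band must be nonnegative, got {additivity_band}")
    d = np.asarray(delta, dtype=float)
    labels = np.full(d.shape, LABEL_ADDITIVE, dtype=object)
    labels[d > additivity_band] = LABEL_SYNERGY
    labels[d < -additivity_band] = LABEL_ANTAGONISM
    return labels


def run_synergy(
    dose_response: DoseResponseMatrix,
    additivity_band: float = 5.0,
    mode: str = "product",
    single_agent_s: np.ndarray | None = None,
    single_agent_p: np.ndarray | None = None,
) -> SynergyResult:
    """Score a full dose-response matrix.

    Single-agent margins are taken from the zero-dose row/column when the
    ladders start at 0; otherwise explicit ``single_agent_s`` /
    ``single_agent_p`` inhibition vectors must be supplied.
    """
    observed = viability_to_inhibition(dose_response.viability)
    margins_from_matrix = False
    if single_agent_s is None and single_agent_p is None:
        if not dose_response.has_zero_dose_margins:
            raise ValueError(
                "cannot locate single-agent margins: the concentration ladders do not "
                "start at dose 0 (no zero-dose row/column). Either supply a matrix whose "
                "first row and column are the single-agent responses, or pass explicit "
                "single_agent_s and single_agent_p inhibition vectors."
            )
        margins_from_matrix = True
        s_margin = observed[:, 0]
        p_margin = observed[0, :]
    elif single_agent_s is not None and single_agent_p is not None:
        s_margin = np.asarray(single_agent_s, dtype=float)
        p_margin = np.asarray(single_agent_p, dtype=float)
        if s_margin.shape != (observed.shape[0],) or p_margin.shape != (observed.shape[1],):
            raise ValueError("explicit single-agent vectors must match the matrix shape")
    else:
        raise ValueError("supply both single_agent_s and single_agent_p, or neither")

    expected = expected_inhibition(s_margin, p_margin, mode=mode)
    if margins_from_matrix:
        # Margin cells are themselves single-agent measurements: the partner at
        # dose 0 contributes no expectation, so expected equals the observed
        # single-agent inhibition there.  The zero-zero cell keeps the formula
        # (typically 0).
        zero_zero = expected[0, 0]
        expected[0, :] = p_margin
        expected[:, 0] = s_margin
        expected[0, 0] = zero_zero

    delta = delta_scores(observed, expected)
    labels = classify_interaction(delta, additivity_band)
    return SynergyResult(
        dose_response=dose_response,
        observed_inhibition=observed,
        expected_inhibition=expected,
        delta=delta,
        labels=labels,
        additivity_band=float(additivity_band),
        mode=mode,
    )


def average_replicates(matrices: list[DoseResponseMatrix]) -> DoseResponseMatrix:
    """Average viability per cell across replicate matrices (same ladders)."""
    if not matrices:
        raise ValueError("no matrices supplied")
    first = matrices[0]
    for m in matrices[1:]:
        if m.drug_s_concs != first.drug_s_concs or m.drug_p_concs != first.drug_p_concs:
            raise ValueError("replicate matrices must share concentration ladders")
    mean_v = np.mean([m.viability for m in matrices], axis=0)
    return DoseResponseMatrix(
        first.drug_s_concs, first.drug_p_concs, mean_v, first.drug_s_name, first.drug_p_name
    )


def read_dose_response_csv(path, drug_s_name: str | None = None, drug_p_name: str | None = None,
                           sep: str | None = None) -> DoseResponseMatrix:
    """Read a viability matrix from delimited text.

    First row = drug P concentrations, first column = drug S concentrations,
    body = viability %.  The top-left header cell may carry the drug names as
    ``"S_name/P_name"``.
    """
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    header = str(df.index.name) if df.index.name is not None else ""
    if drug_s_name is None or drug_p_name is None:
        if "/" in header:
            s_lab, _, p_lab = header.partition("/")
            drug_s_name = drug_s_name or s_lab.strip()
            drug_p_name = drug_p_name or p_lab.strip()
        else:
            drug_s_name = drug_s_name or "drug_S"
            drug_p_name = drug_p_name or "drug_P"
    try:
        s_concs = [float(x) for x in df.index]
        p_concs = [float(x) for x in df.columns]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"concentration labels must be numeric: {exc}") from exc
    return DoseResponseMatrix(tuple(s_concs), tuple(p_concs), df.to_numpy(dtype=float),
                              drug_s_name, drug_p_name)


def write_synergy_tables(result: SynergyResult, out_dir) -> dict[str, str]:
    """Write the long-format table and the square delta matrix as CSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    long_path = os.path.join(out_dir, "synergy_long.csv")
    delta_path = os.path.join(out_dir, "synergy_delta_matrix.csv")
    result.to_long_table().to_csv(long_path, index=False)
    drm = result.dose_response
    result.delta_frame().to_csv(
        delta_path, index_label=f"{drm.drug_s_name}/{drm.drug_p_name}"
    )
    return {"long": long_path, "delta_matrix": delta_path}


def plot_delta_heatmap(result: SynergyResult, path, annotate: bool = True) -> None:
    """Delta-score heatmap with a diverging palette: blue = antagonism,
    orange = synergy, white near zero.  Each cell is annotated with its
    delta value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list(
        "antagonism_synergy", ["#2166ac", "#f7f7f7", "#e08214"]
    )
    d = result.delta
    lim = max(np.max(np.abs(d)), 1e-9)
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * d.shape[1], 1.0 + 0.7 * d.shape[0]))
    im = ax.imshow(d, cmap=cmap, norm=TwoSlopeNorm(vcenter=0.0, vmin=-lim, vmax=lim),
                   aspect="auto", origin="lower")
    drm = result.dose_response
    ax.set_xticks(range(d.shape[1]), [f"{c:g}" for c in drm.drug_p_concs])
    ax.set_yticks(range(d.shape[0]), [f"{c:g}" for c in drm.drug_s_concs])
    ax.set_xlabel(f"{drm.drug_p_name} (µM)")
    ax.set_ylabel(f"{drm.drug_s_name} (µM)")
    ax.set_title("Delta synergy score")
    if annotate:
        for i in range(d.shape[0]):
            for j in range(d.shape[1]):
                ax.text(j, i, f"{d[i, j]:.1f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="delta (pp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
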