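import numpy as np
import pandas as pd
import pytest

from synprot.io import ProteinQuantTable
from synprot.simulate import SynthConfig, synth_tmt


def write_protein_groups_text(path, rows, channels):
    """Write a minimal proteinGroups-dialect file.

    ``rows`` is a list of dicts with keys id, gene, intensities (list),
    and optional marker flags reverse/contaminant/site ("+" when set).
    """
    header = ["Protein IDs", "Gene names"]
    header += [f"Reporter intensity corrected {c}" for c in channels]
    header += ["Reverse", "Potential contaminant", "Only identified by site"]
    lines = ["\t".join(header)]
    for row in rows:
        fields = [row["id"], row.get("gene", "")]
        fields += [str(v) for v in row["intensities"]]
        fields += [row.get("reverse", ""), row.get("contaminant", ""), row.get("site", "")]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_quant_table():
    """6 proteins x 6 samples (3 CTL vs 3 PS, batch 1), linear scale."""
    rng = np.random.default_rng(42)
    samples = [f"b1_CTL_{i}" for i in range(1, 4)] + [f"b1_PS_{i}" for i in range(1, 4)]
    ids = [f"PROT{i}" for i in range(6)]
    intensities = pd.DataFrame(
        np.exp2(rng.normal(20, 1, (6, 6))), index=pd.Index(ids, name="protein_id"),
        columns=samples,
    )
    genes = pd.Series([f"GENE{i}" for i in range(6)], index=intensities.index)
    design = pd.DataFrame(
        {"condition": ["CTL"] * 3 + ["PS"] * 3, "batch": [1] * 6},
        index=pd.Index(samples, name="sample"),
    )
    return ProteinQuantTable(intensities=intensities, gene_symbols=genes).with_design(design)


@pytest.fixture(scope="session")
def default_tmt():
    """One seeded draw of the default TMT generator (2000 proteins)."""
    return synth_tmt(SynthConfig(seed=7))
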