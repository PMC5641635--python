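import pandas as pd
import pytest

from codonquant import (AnalysisOptions, PipelineConfig, SimulationConfig,
                        count_codons, run_stages_in_memory)
from codonquant.mapping import PROFILE_META_COLUMNS


@pytest.fixture(scope="session")
def small_result():
    """One full in-memory pipeline run on a small synthetic dataset."""
    cfg = PipelineConfig(
        seed=11,
        simulation=SimulationConfig(n_proteins=60, seed=11),
        analysis=AnalysisOptions(run_regression=False))
    return run_stages_in_memory(cfg)


@pytest.fixture
def make_profiles():
    """Factory: {peptide: [codon, ...]} -> codon-profile DataFrame."""

    def build(codon_lists, protein_id="PROT1"):
        rows = []
        for pep, codons in codon_lists.items():
            counts = count_codons(codons)
            row = {"peptide": pep, "protein_id": protein_id,
                   "start_aa": 0, "length": len(codons)}
            row.update(counts.to_dict())
            rows.append(row)
        df = pd.DataFrame(rows)
        return df[PROFILE_META_COLUMNS
                  + [c for c in df.columns if c not in PROFILE_META_COLUMNS]]

    return build
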