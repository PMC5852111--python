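import pytest

from coldmem import identification, quantify
from coldmem.synthdata import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_proteins=80, seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """(proteome, truths-by-genotype, PSM table) for a small two-genotype run."""
    return generate_study(small_cfg)


@pytest.fixture(scope="session")
def small_psms_a(small_study):
    _, _, psms = small_study
    return psms[psms["genotype"] == "A"]


@pytest.fixture(scope="session")
def small_filtered_a(small_psms_a):
    return identification.filter_psms(small_psms_a)


@pytest.fixture(scope="session")
def small_quant_a(small_filtered_a):
    inferred = identification.infer_proteins(small_filtered_a)
    qpsms = identification.quantifiable_psms(small_filtered_a, inferred)
    return quantify.add_pvalues(quantify.protein_quant_table(qpsms))
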