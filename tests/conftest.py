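import pytest

from vregions.reference_model import load_ecoli_reference, load_primer_table
from vregions.synthetic import PanelSpec, make_panel


@pytest.fixture(scope="session")
def primer_table():
    return load_primer_table()


@pytest.fixture(scope="session")
def regions(primer_table):
    return {p.region_label: p for p in primer_table}


@pytest.fixture(scope="session")
def ecoli():
    return load_ecoli_reference()


@pytest.fixture(scope="session")
def divergent_panel():
    """Five taxa diverged ~5% per site across the whole gene body."""
    spec = PanelSpec(n_taxa=5, per_region_divergence={"V1-V9": 0.05}, seed=42)
    return make_panel(spec)
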