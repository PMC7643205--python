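import pytest

from molscreen import curation, synthetic


@pytest.fixture(scope="session")
def small_library():
    """60+60 planted-substructure molecules with labels (zero noise)."""
    spec = synthetic.FixtureSpec(n_actives=60, n_inactives=60, seed=11)
    entries, manifest = synthetic.generate_smiles_library(spec)
    return entries, manifest


@pytest.fixture(scope="session")
def default_config():
    return curation.CurationConfig(
        allowed_taxa=frozenset({"Homo sapiens"}), min_actives=5
    )


@pytest.fixture(scope="session")
def toy_records():
    """Six-record table: three conforming, three each failing one filter."""
    mk = lambda **kw: curation.BioactivityRecord(
        compound_id=kw.pop("cid"),
        smiles="CCO",
        target_id="T1",
        standard_value_nm=kw.pop("value", 100.0),
        pchembl=kw.pop("pchembl", 5.0),
        **kw,
    )
    return [
        mk(cid="ok1"),
        mk(cid="bad_assay", assay_type="functional"),
        mk(cid="ok2", value=50000.0),
        mk(cid="bad_type", target_type="other"),
        mk(cid="bad_pchembl", pchembl=None),
        mk(cid="ok3", value=15000.0),
    ]
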