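import pytest

import champterm as ct


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study, shared across tests."""
    config = ct.GeneratorConfig()
    records, cds_records, predictions, evidence, truth = ct.simulate_study(
        config, seed=1
    )
    return {
        "config": config,
        "records": records,
        "proteins": {r.accession: r for r in records},
        "cds": {c.accession: c for c in cds_records},
        "predictions": predictions,
        "evidence": evidence,
        "truth": truth,
    }


@pytest.fixture
def tiny_protein():
    return ct.ProteinRecord(accession="P1", sequence="MASTKLDHRAGE")
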