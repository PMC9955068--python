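import numpy as np
import pytest

from mitosignal import phylo, seqio, synthetic


@pytest.fixture
def tiny_nt_aln() -> seqio.Alignment:
    """Two-gene, four-taxon nucleotide alignment with in-frame partitions."""
    rows = [
        "ATGGCTATTACT",
        "ATGGCGATTACC",
        "ATAGCTATAACT",
        "ATGACTATTACT",
    ]
    pm = {"g1": np.arange(1, 7), "g2": np.arange(7, 13)}
    return seqio.Alignment(
        ["t1", "t2", "t3", "t4"], np.array([list(r) for r in rows]), "nucleotide", pm
    )


@pytest.fixture(scope="session")
def scenario_het():
    cfg = synthetic.make_branchiopod_scenario(seed=0)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def scenario_hom():
    cfg = synthetic.make_branchiopod_scenario(seed=0, heterogeneous=False)
    return synthetic.generate(cfg)


@pytest.fixture
def jc() -> phylo.SubstitutionModel:
    return phylo.SubstitutionModel.jc69()
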