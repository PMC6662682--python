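import pytest

from ggmut import MutationSpec, PAGM22082_CRED, codon_usage, design
from ggmut import fixtures


@pytest.fixture(scope="session")
def ecoli_usage():
    return codon_usage("e_coli")


@pytest.fixture(scope="session")
def saturation_cds():
    """300-codon site-free synthetic CDS (multi-site saturation geometry)."""
    return fixtures.saturation_case_cds()


@pytest.fixture(scope="session")
def saturation_mutations():
    return [
        MutationSpec(p, "saturation", "NDT")
        for p in fixtures.SATURATION_CASE_POSITIONS
    ]


@pytest.fixture(scope="session")
def saturation_design(saturation_cds, saturation_mutations):
    return design(saturation_cds, saturation_mutations, PAGM22082_CRED)


@pytest.fixture(scope="session")
def point_cds():
    """711-nt synthetic CDS with a Leu codon at 69 and an internal BbsI
    site (single point-mutagenesis geometry)."""
    return fixtures.point_case_cds()
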