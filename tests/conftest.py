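import pytest

from vdjkit.config import ScanConfig
from vdjkit.synthetic import LocusSpec, build_locus


@pytest.fixture(scope="session")
def config():
    return ScanConfig()


@pytest.fixture(scope="session")
def locus42():
    """A certified defect-free locus (5 V + 4 J, mixed strands/leader modes)."""
    return build_locus(LocusSpec(seed=42))


@pytest.fixture(scope="session")
def defect_locus():
    """One planted defect per gene, covering every scanner-visible defect."""
    spec = LocusSpec(
        seed=7,
        v_defects={0: "stop_codon", 1: "no_cac", 2: "missing_anchor",
                   3: "spacer_out_of_tolerance"},
        j_defects={0: "stop_codon", 1: "no_cac", 2: "missing_fg",
                   3: "missing_donor"},
    )
    return build_locus(spec)
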