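import numpy as np
import pytest

from dtcprs.genotype_io import VariantCall
from dtcprs.harmonize import POPULATIONS, ReferencePanelSite
from dtcprs.scoring import ScoreMode, ScoreWeight, WeightPanel


def uniform_freqs(f: float) -> dict:
    return {p: f for p in POPULATIONS}


FIVE_SNP_SPEC = [
    # rsid, ref, alt, beta, effect-allele (=alt) frequency
    ("rs1", "A", "G", 0.2, 0.1),
    ("rs2", "C", "T", -0.1, 0.3),
    ("rs3", "G", "A", 0.4, 0.5),
    ("rs4", "T", "C", 0.05, 0.7),
    ("rs5", "A", "C", -0.3, 0.25),
]


@pytest.fixture
def five_snp_sites() -> list[ReferencePanelSite]:
    return [
        ReferencePanelSite(rsid, "1", 1000 * (i + 1), ref, alt, uniform_freqs(f))
        for i, (rsid, ref, alt, _, f) in enumerate(FIVE_SNP_SPEC)
    ]


@pytest.fixture
def five_snp_panel() -> WeightPanel:
    weights = tuple(
        ScoreWeight(rsid, alt, ref, beta, uniform_freqs(f))
        for rsid, ref, alt, beta, f in FIVE_SNP_SPEC
    )
    return WeightPanel("toy_trait", ScoreMode.TOP_SNP, weights)


@pytest.fixture
def person_calls() -> list[VariantCall]:
    """Alt-allele dosages 2, 1, 0, 1 at rs1-rs4; rs5 is a vendor no-call."""
    return [
        VariantCall("rs1", "1", 1000, ("G", "G")),
        VariantCall("rs2", "1", 2000, ("C", "T")),
        VariantCall("rs3", "1", 3000, ("G", "G")),
        VariantCall("rs4", "1", 4000, ("T", "C")),
        VariantCall("rs5", "1", 5000, None),
    ]
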