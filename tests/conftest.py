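import numpy as np
import pytest

from pepscreen import (
    InterfaceComplex,
    InterfaceFixture,
    Segment,
    build_cterm_library,
    gen_proteome,
)

# Synthetic stand-in for the CHMP2B C-terminal region: the printed lead-hit
# context DEEIERQLKALG embedded in random flanking sequence.
CHMP2B_LIKE_CHAIN = "MSNWFKQAEPRTVYGH" + "DEEIERQLKALG" + "KSPDAVTMNQRWEYFH"
LEAD_PEPTIDE = "IPIQLKA"


@pytest.fixture(scope="session")
def small_proteome():
    return gen_proteome(50, (20, 120), seed=7)


@pytest.fixture(scope="session")
def small_library(small_proteome):
    return build_cterm_library(small_proteome, k=7)


@pytest.fixture()
def chmp2b_fixture():
    """Hand-built two-complex fixture: a CHMP2B/VPS4B-like complex carrying
    the lead-hit interface segment plus a decoy complex."""
    target = InterfaceComplex(
        complex_id="2JQK",
        partners=("CHMP2B", "VPS4B"),
        segments=[
            Segment(partner="CHMP2B", sequence="DEEIERQLKALG", start=17),
            Segment(partner="VPS4B", sequence="WQDKLHNAYRTS", start=5),
        ],
        chain_sequences={
            "CHMP2B": CHMP2B_LIKE_CHAIN,
            "VPS4B": "MHAY" + "WQDKLHNAYRTS" + "PLGVKDME",
        },
    )
    decoy = InterfaceComplex(
        complex_id="9ZZZ",
        partners=("DEC1", "DEC2"),
        segments=[
            Segment(partner="DEC1", sequence="MMMMWWWWCCCC", start=1),
            Segment(partner="DEC2", sequence="HHHHYYYYFFFF", start=1),
        ],
        chain_sequences={"DEC1": "MMMMWWWWCCCC", "DEC2": "HHHHYYYYFFFF"},
    )
    fx = InterfaceFixture(
        complexes=[target, decoy],
        annotations={
            "CHMP2B": {"GO:1", "GO:2", "GO:5"},
            "VPS4B": {"GO:1", "GO:2", "GO:7"},
            "DEC1": {"GO:3"},
            "DEC2": {"GO:4"},
        },
        pd_terms={"GO:1", "GO:2", "GO:3", "GO:4"},
    )
    fx.validate()
    return fx


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
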