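import pytest

from beditseq import build_reference, demo_reference

# Protospacer with an octacytidine 5' run; the amplicon base immediately 5' of
# the protospacer is also C, giving nine consecutive target Cs at offsets
# -21..-13 — the worst-case poly-C motif for editing-window assays.
POLYC_PROTO = "CCCCCCCC" + "GATTGAGTAAGT"
POLYC_LEFT = "GATTACAGGTTAGCAAGTG" + "C"
POLYC_RIGHT = "TGGATCAACGTTGAGCTTAG"


@pytest.fixture(scope="session")
def demo_ref():
    """Small heteropolymeric reference (target Cs at -19, -18, -16)."""
    return demo_reference()


@pytest.fixture(scope="session")
def polyc_ref():
    """Reference with nine consecutive target Cs at offsets -21..-13."""
    amplicon = POLYC_LEFT + POLYC_PROTO + "TGG" + POLYC_RIGHT
    return build_reference(amplicon, POLYC_PROTO, region_halfwidth=3, flank_len=10)


@pytest.fixture(scope="session")
def polyc_targets(polyc_ref):
    return polyc_ref.target_cytidines(within="region")
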