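import pytest

from codonecon import (
    NITROGEN,
    build_features,
    default_rules,
    hypothetical_inventory,
    standard_code,
    tai_table,
)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def full_tai(code):
    return tai_table(hypothetical_inventory("full", code), default_rules(), code)


@pytest.fixture(scope="session")
def s2_tai(code):
    return tai_table(hypothetical_inventory("strategy2", code), default_rules(), code)


@pytest.fixture(scope="session")
def features(code, full_tai):
    return build_features(NITROGEN, full_tai, code)


@pytest.fixture(scope="session")
def s2_features(code, s2_tai):
    return build_features(NITROGEN, s2_tai, code)


TRNASCAN_FIXTURE = "\n".join(
    [
        "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf",
        "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore",
        "--------\t------\t-----\t---\t----\t-----\t-----\t----\t------",
        "chr1\t1\t1000\t1072\tAla\tTGC\t0\t0\t55.1",
        "chr1\t2\t2000\t2072\tAla\tTGC\t0\t0\t61.3",
        "chr1\t3\t3000\t3072\tMet\tCAT\t0\t0\t70.0",
        "chr1\t4\t4000\t4072\tMet\tCAT\t0\t0\t68.2",
        "chr1\t5\t5000\t5072\tGly\tGCC\t0\t0\t50.0",
        "chr1\t6\t6000\t6072\tUndet\tNNN\t0\t0\t30.0",
        "chr1\t7\t7000\t7072\tPseudo\tGAA\t0\t0\t20.0\t\tpseudo",
    ]
) + "\n"


@pytest.fixture
def trnascan_file(tmp_path):
    p = tmp_path / "trnascan.out"
    p.write_text(TRNASCAN_FIXTURE)
    return p
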