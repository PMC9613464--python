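from pathlib import Path

import pytest

from lsckit import io
from lsckit.lda import LDAssay

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table2_assay() -> LDAssay:
    """The printed 12-week dilution series for the CD34+CD38- fraction."""
    return io.read_assay(DATA / "table2_assay.csv")


@pytest.fixture(scope="session")
def chr11q_segments():
    """Reference segment boundaries of the chr11q amplification ladder."""
    return io.read_bed(DATA / "chr11q_segments.bed")
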