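import numpy as np
import pysam
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_read(seq: str, ref_start: int = 0, chrom: str = "chr1",
              reverse: bool = False, mapq: int = 60,
              header: pysam.AlignmentHeader | None = None) -> pysam.AlignedSegment:
    """A fully matched single-end alignment for hand-built examples."""
    if header is None:
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": 1_000_000}]}
        )
    a = pysam.AlignedSegment(header)
    a.query_name = "r"
    a.query_sequence = seq
    a.flag = 16 if reverse else 0
    a.reference_id = 0
    a.reference_start = ref_start
    a.mapping_quality = mapq
    a.cigartuples = [(0, len(seq))]
    return a


@pytest.fixture(scope="session")
def reference_50k() -> str:
    from relicdx.synthetic_data import random_reference

    return random_reference(50_000, seed=12345)


def binomial_se(p: float, n: float) -> float:
    return float(np.sqrt(max(p * (1 - p), 1e-12) / n))
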