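import numpy as np
import pytest

from adenomaevo.variant_io import SomaticCall


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture()
def reference():
    """Tiny in-memory reference: chr1 with a homopolymer run at 101-104."""
    seq = list("ACGTACGTAC" * 30)
    # positions (1-based): 100 = C, 101-104 = AAAA, 105 = G
    seq[99] = "C"
    seq[100:104] = list("AAAA")
    seq[104] = "G"
    return {"chr1": "".join(seq)}


def make_call(
    chrom="chr1",
    pos=10,
    ref="A",
    alt="T",
    caller="varscan2",
    patient="P1",
    sample_type="tissue",
    vaf=0.3,
    depth=1000,
    alt_reads=None,
    **kwargs,
):
    if alt_reads is None:
        alt_reads = round(vaf * depth)
    return SomaticCall(
        patient_id=patient,
        sample_type=sample_type,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        caller=caller,
        vaf=alt_reads / depth if depth else 0.0,
        depth=depth,
        alt_reads=alt_reads,
        **kwargs,
    )


@pytest.fixture()
def call_factory():
    return make_call
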