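import pytest

from poolscan import GenomeLayout, PoolData, VariantRecord

#: INFO values comfortably inside the pass region of every hard filter.
PASS_INFO = {
    "QD": 20.0,
    "MQ": 55.0,
    "FS": 5.0,
    "HaplotypeScore": 2.0,
    "MQRankSum": 0.5,
    "ReadPosRankSum": 0.25,
}


def make_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alts=("G",),
    qual=200.0,
    info=None,
    pools=None,
    ploidy=60,
    n_alt=10,
):
    """A valid passing record with one 60-ploid pool unless overridden."""
    if info is None:
        info = dict(PASS_INFO)
    if pools is None:
        gt = (0,) * (ploidy - n_alt) + (1,) * n_alt
        depths = tuple([12] + [8] * len(alts))
        pools = (PoolData(depths, gt, 60),)
    return VariantRecord(chrom, pos, ref, tuple(alts), qual, info, tuple(pools))


@pytest.fixture
def layout():
    return GenomeLayout((("chr1", 2_500_000), ("chr2", 1_200_000)))


@pytest.fixture
def record_factory():
    return make_record
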