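import pytest

from radmut.records import Category, MutationEvent, SvKind, Zygosity
from radmut.synthetic_data import make_genome


@pytest.fixture(scope="session")
def genome():
    return make_genome(120_000, 0.36, seed=11, n_chroms=2)


def mk_event(
    sample="P1",
    chrom="chr1",
    start=100,
    end=None,
    category=Category.SBS,
    net_length=0,
    zygosity=Zygosity.HET,
    **kwargs,
):
    """Terse MutationEvent factory for tests."""
    if end is None:
        end = start if net_length >= 0 else start - net_length - 1
    if category is Category.SV and "sv_kind" not in kwargs:
        kwargs["sv_kind"] = SvKind.INVERSION
    return MutationEvent(
        sample_id=sample,
        chrom=chrom,
        start=start,
        end=end,
        category=category,
        net_length=net_length,
        zygosity=zygosity,
        **kwargs,
    )


@pytest.fixture
def event_factory():
    return mk_event
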