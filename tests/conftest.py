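import pytest
from hypothesis import settings

from hivemzt.core import AlignmentRecord, GenomicInterval
from hivemzt.pipeline import make_demo

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def make_record(
    chrom="chr1",
    blocks=((100, 150),),
    read_id="r1",
    sample_id="s1",
    soft_clip_5="",
    soft_clip_3="",
    sequence=None,
):
    """Hand-built alignment record for unit tests."""
    ivs = [GenomicInterval(chrom, s, e) for s, e in blocks]
    aligned = "G" * sum(e - s for s, e in blocks)
    seq = sequence if sequence is not None else soft_clip_5 + aligned + soft_clip_3
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        blocks=ivs,
        soft_clip_5=soft_clip_5,
        soft_clip_3=soft_clip_3,
        read_sequence=seq,
        sample_id=sample_id,
    )


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """One default-configuration simulated dataset run end to end.

    Shared across the whole session: the synthetic study design (two
    queens, three embryos per sex and timepoint at 24/48/72 h) with the
    full pipeline and its truth-recovery report.
    """
    outdir = tmp_path_factory.mktemp("demo")
    dataset, result, report = make_demo(seed=11, outdir=outdir)
    return {
        "dataset": dataset,
        "result": result,
        "report": report,
        "outdir": outdir,
    }
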