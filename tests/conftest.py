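import numpy as np
import pytest

from sporesnp import (
    IntervalSet,
    ObservationMatrix,
    ReferenceModel,
    Site,
    SiteAnnotations,
)


def make_annotations(
    n,
    qd=25.0,
    fs=2.0,
    mq=55.0,
    mqrs=0.0,
    rprs=0.0,
    qual=500.0,
    sor=1.0,
    mqrs_missing=False,
    rprs_missing=False,
):
    """All-nominal annotations with scalar or per-site overrides."""
    full = lambda v: np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)
    flags = lambda v: np.full(n, v, dtype=bool) if np.isscalar(v) else np.asarray(v, bool)
    return SiteAnnotations(
        qd=full(qd),
        fs=full(fs),
        mq=full(mq),
        mq_rank_sum=full(mqrs),
        mq_rank_sum_missing=flags(mqrs_missing),
        read_pos_rank_sum=full(rprs),
        read_pos_rank_sum_missing=flags(rprs_missing),
        qual=full(qual),
        sor=full(sor),
    )


def make_obs(depth, ref_count, alt_count, contig="contig_1"):
    """ObservationMatrix from (n_sites, n_nuclei) arrays; sites 1..n."""
    depth = np.atleast_2d(np.asarray(depth))
    n_sites, n_nuclei = depth.shape
    sites = [Site(contig, i + 1, "A", "T") for i in range(n_sites)]
    return ObservationMatrix(
        sites=sites,
        depth=depth,
        ref_count=np.atleast_2d(np.asarray(ref_count)),
        alt_count=np.atleast_2d(np.asarray(alt_count)),
        nucleus_ids=[f"nucleus_{j}" for j in range(n_nuclei)],
    )


@pytest.fixture
def small_reference():
    return ReferenceModel(
        contigs=(("contig_1", 50_000), ("contig_2", 30_000)),
        repeat_intervals=IntervalSet.from_records(
            [("contig_1", 10_000, 20_000), ("contig_2", 0, 5_000)]
        ),
        coding_intervals=IntervalSet.from_records(
            [("contig_1", 25_000, 35_000)]
        ),
    )
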