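import pytest

from phagemosaic import SimulationConfig, run_pipeline, simulate
from phagemosaic.io import AlignmentHit


def make_hit(
    q="A",
    s="B",
    p=0.99,
    pid=0.5,
    qs=1,
    qe=100,
    ss=1,
    se=100,
    qlen=200,
    slen=200,
    tag="self",
):
    return AlignmentHit(
        query_id=q,
        subject_id=s,
        probability=p,
        percent_identity=pid,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        q_len=qlen,
        s_len=slen,
        search_tag=tag,
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Default study-condition bundle: 200 rHMMs, 20+20 planted mosaic
    pairs, 15 planted families, no noise."""
    return simulate(SimulationConfig(seed=20))


@pytest.fixture(scope="session")
def noiseless_result(noiseless_bundle):
    b = noiseless_bundle
    return run_pipeline(
        b.self_hits,
        b.ecod_hits,
        b.phrog_hits,
        b.antidefence_hits,
        b.ecod_map,
        b.function_map,
        rhmm_ids=b.truth.architectures,
    )
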