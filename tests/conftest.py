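import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from godiverge.ortholog_qc import Indel, TranscriptMapping


def _mapping(tid, **kw):
    base = dict(
        transcript_id=tid,
        gene_id=tid.split(".")[0],
        coding_length=900,
        coverage_fraction=0.95,
        lowqual_fraction=0.02,
        indels=(),
        in_frame_stop=False,
        splice_sites_conserved=True,
    )
    base.update(kw)
    return TranscriptMapping(**base)


@pytest.fixture(scope="session")
def qc_boundary_fixture():
    """12 hand-built transcript mappings covering every QC criterion boundary,
    with the hand-derived set of passing transcript ids."""
    mappings = [
        _mapping("t01"),                                     # clean -> pass
        _mapping("t02", coverage_fraction=0.80),             # coverage boundary, inclusive -> pass
        _mapping("t03", coverage_fraction=0.79),             # just below coverage -> fail a
        _mapping("t04", lowqual_fraction=0.10),              # lowqual boundary, inclusive -> pass
        _mapping("t05", lowqual_fraction=0.11),              # just above -> fail b
        _mapping("t06", indels=(Indel(100, 1),)),            # isolated frame-shift -> fail c
        _mapping("t07", indels=(Indel(100, 1), Indel(108, -1))),  # compensated, net 0 -> pass
        _mapping("t08", indels=(Indel(100, 1), Indel(130, 2))),   # two clusters, both shifted -> fail c
        _mapping("t09", indels=(Indel(100, 1), Indel(110, 2))),   # one cluster, net +3 -> pass
        _mapping("t10", indels=(Indel(0, 1), Indel(10, 1), Indel(20, 1))),  # chained, net +3 -> pass
        _mapping("t11", in_frame_stop=True),                 # fail d
        _mapping("t12", splice_sites_conserved=False),       # fail d
    ]
    expected_pass = {"t01", "t02", "t04", "t07", "t09", "t10"}
    return mappings, expected_pass


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
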