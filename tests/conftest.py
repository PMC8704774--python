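import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_alignment():
    from p74kit.seqio import Alignment, SequenceRecord

    return Alignment(
        [
            SequenceRecord("s1", "MCVLKWDPAG", "protein"),
            SequenceRecord("s2", "MCILKWDPAG", "protein"),
            SequenceRecord("s3", "MCVLRWDPAG", "protein"),
        ]
    )


@pytest.fixture
def toy_orf():
    """ATG TGG GAT CCG TAA -> protein MWDP (WDP with a natural BamHI site)."""
    from p74kit.chimera import OrfRecord

    return OrfRecord("toy", "ATGTGGGATCCGTAA")
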