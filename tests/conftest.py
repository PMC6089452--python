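import warnings

import pytest
from hypothesis import settings

from leaderscan import TranscriptLeaderRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def make_record():
    """Factory for records with a stop-rich default downstream context."""

    def _make(tl, ds="ATGAAGGGTTAACCTAAGGG", gene_id="g1", **kw):
        return TranscriptLeaderRecord(gene_id, tl, ds, **kw)

    return _make


@pytest.fixture(autouse=True)
def _quiet_non_atg_warning():
    # records built from arbitrary genome slices legitimately lack a leading ATG
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*does not begin with ATG")
        yield
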