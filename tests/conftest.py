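import numpy as np
import pytest

from amygconn.cohort import SubjectRecord


@pytest.fixture
def make_record():
    """Factory for a minimal valid SubjectRecord with a chosen connectivity value."""

    def _make(conn=0.0, subject_id="sub-000", **kw):
        defaults = dict(
            subject_id=subject_id,
            group="immediate",
            sessions_completed=16,
            baseline_lsas=80.0,
            lsas_series=np.array([70.0, 60.0, 50.0]),
            post_lsas=50.0,
            delta_lsas=30.0,
            true_composite_conn=conn,
        )
        defaults.update(kw)
        return SubjectRecord(**defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
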