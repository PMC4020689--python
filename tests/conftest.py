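from datetime import date

import pytest

from radshift import CommunitySample, TrapCatchRecord


def make_sample(abundance, site="s1", period="1980", raw=None):
    """Build a CommunitySample directly from an aAD map."""
    return CommunitySample(
        site=site,
        period=period,
        n_traps=1,
        exposure_days=10.0,
        abundance=dict(abundance),
        raw_counts=dict(raw) if raw else {},
    )


def make_record(**kwargs):
    defaults = dict(
        site="s1",
        period="1980",
        trap="t1",
        interval_start=date(1980, 6, 15),
        interval_end=date(1980, 7, 15),
        species="spA",
        count=1,
    )
    defaults.update(kwargs)
    return TrapCatchRecord(**defaults)


@pytest.fixture
def sample_factory():
    return make_sample


@pytest.fixture
def record_factory():
    return make_record
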