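import datetime as dt

import pytest

from emafit.protocol import default_protocol
from emafit.simulate import TZ


@pytest.fixture(scope="session")
def v2():
    return default_protocol("v2.0", 14)


@pytest.fixture(scope="session")
def alpha():
    return default_protocol("alpha", 14)


@pytest.fixture()
def clock():
    """Local timestamps on a fixed study day."""

    def at(day: int, hour: int, minute: int = 0) -> dt.datetime:
        base = dt.datetime(2024, 3, 4, tzinfo=TZ) + dt.timedelta(days=day)
        return base + dt.timedelta(hours=hour, minutes=minute)

    return at
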