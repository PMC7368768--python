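import datetime as dt
import itertools

import pytest

from mpindex import MPIStore, generate_ssn


def make_row(first="Anna", last="Muller", birth="01/01/1990", sex="F",
             ssn=None, seq=0, **extra):
    """Build a valid raw trait map; ssn=True derives one from the birth date."""
    row = {
        "first_name": first, "last_name": last,
        "birth_date": birth, "sex": sex,
        "ssn": "",
    }
    if ssn is True:
        day, month, year = (int(p) for p in birth.split("/"))
        row["ssn"] = generate_ssn(dt.date(year, month, day), seq).raw
    elif isinstance(ssn, str):
        row["ssn"] = ssn
    row.update(extra)
    return row


class TickClock:
    """Deterministic clock advancing one second per call."""

    def __init__(self, start=dt.datetime(2018, 1, 1)):
        self._ticks = itertools.count()
        self._start = start

    def __call__(self):
        return self._start + dt.timedelta(seconds=next(self._ticks))


@pytest.fixture
def clock():
    return TickClock()


@pytest.fixture
def store(clock):
    """Seeded store with the usual domain layout."""
    store = MPIStore(seed=42, clock=clock)
    store.register_domain("ccss", "REFERENCE", "national registry")
    store.register_domain("hospA", "SECONDARY", "hospital A")
    store.register_domain("portal", "CONSUMER", "platform service")
    return store
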