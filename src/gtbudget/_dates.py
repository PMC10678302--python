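"""Calendar helpers: the simulation clock is indexed in whole months with
month 0 = January 2020."""

from __future__ import annotations

import datetime as _dt

SIM_START = _dt.date(2020, 1, 1)


def month_index(d: _dt.date, start: _dt.date = SIM_START) -> int:
    """Index of the calendar month containing ``d``, relative to ``start``."""
    return (d.year - start.year) * 12 + (d.month - start.month)


def add_days(d: _dt.date, days: float) -> _dt.date:
    """Shift a date by a (possibly fractional) number of days."""
    return d + _dt.timedelta(days=float(days))
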