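"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by the most naive route available
(scanning, counting, direct dict lookup) and must stay independent of
the implementations they check.
"""

from __future__ import annotations

import datetime as dt


def brute_force_closest(records, recruitment: dt.date):
    """Scan all records for the minimal |date - recruitment|; on a tie
    prefer the earlier date."""
    best = None
    best_key = None
    for r in records:
        delta = (r.record_date - recruitment).days
        key = (abs(delta), 0 if delta <= 0 else 1)
        if best is None or key < best_key:
            best, best_key = r, key
    return best


def whole_months_between(start: dt.date, end: dt.date) -> int:
    """Count whole months by stepping month anniversaries from *start*.

    The m-th anniversary clamps the day into the target month (Jan 31 ->
    Feb 28), matching elapsed-month counting on real calendars.
    """
    assert start <= end
    months = 0
    while _add_months(start, months + 1) <= end:
        months += 1
    return months


def _add_months(d: dt.date, m: int) -> dt.date:
    year = d.year + (d.month - 1 + m) // 12
    month = (d.month - 1 + m) % 12 + 1
    day = d.day
    while True:
        try:
            return dt.date(year, month, day)
        except ValueError:
            day -= 1


def whole_years_between(birth: dt.date, ref: dt.date) -> int:
    """Count completed birthdays one by one."""
    years = 0
    while _add_months(birth, 12 * (years + 1)) <= ref:
        years += 1
    return years


def naive_points(defn_dict: dict, row: dict) -> int:
    """Re-evaluate a points definition straight from its dict form."""
    total = 0
    for rule in defn_dict["rules"]:
        var = rule["variable"]
        if rule["type"] == "category":
            total += rule["points"][row[var]]
            continue
        if "strata" in rule:
            sval = row[rule["stratify_by"]]
            bands = None
            for s in rule["strata"]:
                lo = s["stratum"].get("lo")
                hi = s["stratum"].get("hi")
                if (lo is None or sval >= lo) and (hi is None or sval < hi):
                    bands = s["bands"]
                    break
            assert bands is not None
        else:
            bands = rule["bands"]
        value = row[var]
        matched = None
        for b in bands:
            lo, hi = b.get("lo"), b.get("hi")
            if (lo is None or value >= lo) and (hi is None or value < hi):
                matched = b["points"]
                break
        assert matched is not None
        total += matched
    return total
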