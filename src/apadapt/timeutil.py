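"""Clock-time conventions shared across the package.

Times of day are minutes from midnight on a 5-minute grid; intervals are
half-open ``[start, end)`` and may wrap across midnight.
"""

from __future__ import annotations

MINUTES_PER_DAY = 1440
STEP_MIN = 5
STEPS_PER_DAY = MINUTES_PER_DAY // STEP_MIN  # 288
STEPS_PER_HOUR = 60 // STEP_MIN  # 12


def hhmm(minutes: float) -> str:
    """Format minutes-from-midnight as HH:MM (for reports and logs)."""
    m = int(minutes) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


def in_interval(t: float, start: float, end: float) -> bool:
    """True if clock time ``t`` lies in the half-open daily interval
    ``[start, end)``, wrapping across midnight when ``end <= start``."""
    t = t % MINUTES_PER_DAY
    if start < end:
        return start <= t < end
    return t >= start or t < end


def interval_length(start: float, end: float) -> float:
    return (end - start) % MINUTES_PER_DAY or MINUTES_PER_DAY


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Whether two wrapping half-open daily intervals intersect."""
    # Split wrapped intervals at midnight and test linear overlap.
    def split(iv):
        s, e = iv
        if s < e:
            return [(s, e)]
        return [(s, MINUTES_PER_DAY), (0.0, e)]

    for s1, e1 in split(a):
        for s2, e2 in split(b):
            if max(s1, s2) < min(e1, e2):
                return True
    return False
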