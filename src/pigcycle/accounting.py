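"""Small bookkeeping helpers: dataset partition counts and labor accounting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["partition_counts", "LaborComparison", "labor_comparison"]


def partition_counts(n_items: int, ratios: Sequence[float] = (8, 1, 1)) -> tuple[int, ...]:
    """Split ``n_items`` into integer parts proportional to ``ratios``.

    Largest-remainder apportionment: exact when the ratios divide evenly
    (6420 at 8:1:1 gives 5136/642/642), otherwise leftover items go to the
    parts with the largest fractional share.  Parts always sum to n_items.
    """
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    total = sum(ratios)
    if total <= 0 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative with a positive sum")
    exact = [n_items * r / total for r in ratios]
    counts = [int(x) for x in exact]
    shortfall = n_items - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:shortfall]:
        counts[i] += 1
    return tuple(counts)


@dataclass(frozen=True)
class LaborComparison:
    manual_hours: float
    automated_hours: float

    @property
    def hours_saved(self) -> float:
        return self.manual_hours - self.automated_hours

    @property
    def saving_pct(self) -> float:
        return self.hours_saved / self.manual_hours * 100.0


def labor_comparison(
    manual_hours_per_day: float, automated_minutes_per_day: float, days: int
) -> LaborComparison:
    """Total weighing labor under manual vs camera-based monitoring.

    Example: 2 h/day manual vs 15 min/day automated over 150 days gives
    300 h vs 37.5 h, an 87.5% saving.
    """
    if days <= 0 or manual_hours_per_day <= 0 or automated_minutes_per_day < 0:
        raise ValueError("need positive days and manual hours, non-negative automated minutes")
    return LaborComparison(
        manual_hours=manual_hours_per_day * days,
        automated_hours=automated_minutes_per_day / 60.0 * days,
    )
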