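"""Stage-based rations and dynamic precision-feeding adjustments.

Growing pigs move through four ration stages keyed to live weight
(weaning, then three fattening stages); each stage fixes the feed mix
(corn / soybean meal / wheat bran / compound-and-concentrate percentages)
and the feeding frequency.  On top of the static table sit two dynamic
rules driven by real-time weight estimates:

* rapid-growth band (30-80 kg): raise corn to 68% and soybean meal to the
  18-20% band (midpoint 19% by default) to feed the growth spurt;
* slow growers (average daily gain below 0.6 kg/day): raise soybean meal
  to 20% and add 2% fishmeal to close the protein gap.

The slow-grower rule is corrective and takes precedence when both fire.
After any rule the untouched ingredients are rescaled pro-rata so the mix
still sums to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Ration",
    "StageTable",
    "DEFAULT_STAGE_TABLE",
    "classify_stage",
    "daily_gain",
    "adjust_ration",
    "plan_feed_quantity",
]

RATION_SUM_TOL = 0.01


@dataclass(frozen=True)
class Ration:
    """Feed mix in percent of mass, plus meals per day."""

    corn: float
    soybean_meal: float
    wheat_bran: float
    compound_and_other: float
    fishmeal: float = 0.0
    feeds_per_day: int = 3
    rebalance_clamped: bool = False

    def __post_init__(self) -> None:
        comps = self.components()
        if any(v < 0 for v in comps.values()):
            raise ValueError(f"negative ration component: {comps}")
        total = sum(comps.values())
        if abs(total - 100.0) > RATION_SUM_TOL:
            raise ValueError(f"ration sums to {total}, expected 100")

    def components(self) -> dict[str, float]:
        return {
            "corn": self.corn,
            "soybean_meal": self.soybean_meal,
            "wheat_bran": self.wheat_bran,
            "compound_and_other": self.compound_and_other,
            "fishmeal": self.fishmeal,
        }


@dataclass(frozen=True)
class Stage:
    label: str
    lo: float  # inclusive
    hi: float  # exclusive; inf for the open top stage
    ration: Ration


@dataclass(frozen=True)
class StageTable:
    """Ordered, non-overlapping half-open weight intervals [lo, hi)."""

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage table is empty")
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.lo != prev.hi:
                raise ValueError(
                    f"stages '{prev.label}' and '{cur.label}' do not tile: "
                    f"{prev.hi} != {cur.lo}"
                )
        if self.stages[-1].hi != float("inf"):
            raise ValueError("last stage must be open-ended")


# The printed stage boundaries leave 0.1 kg gaps (15.0->15.1, 40.0->40.1,
# 80.0->80.1); the half-open intervals below are centred on those gaps so
# every positive weight maps to exactly one stage.
DEFAULT_STAGE_TABLE = StageTable(
    stages=(
        Stage("Weaning Period", 7.0, 15.05,
              Ration(corn=60, soybean_meal=20, wheat_bran=5, compound_and_other=15, feeds_per_day=7)),
        Stage("Fattening Stage I", 15.05, 40.05,
              Ration(corn=60, soybean_meal=22, wheat_bran=10, compound_and_other=8, feeds_per_day=3)),
        Stage("Fattening Stage II", 40.05, 80.05,
              Ration(corn=65, soybean_meal=18, wheat_bran=13, compound_and_other=4, feeds_per_day=3)),
        Stage("Fattening Stage III", 80.05, float("inf"),
              Ration(corn=67, soybean_meal=15, wheat_bran=14, compound_and_other=4, feeds_per_day=3)),
    )
)


def classify_stage(weight: float, table: StageTable = DEFAULT_STAGE_TABLE) -> str:
    """Map a live weight (kg) to its unique growth stage label.

    Weights below the first interval (pre-weaning) map to the first stage
    with a warning.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    first = table.stages[0]
    if weight < first.lo:
        warnings.warn(
            f"weight {weight} kg below the first stage ({first.lo} kg); using '{first.label}'",
            stacklevel=2,
        )
        return first.label
    for stage in table.stages:
        if stage.lo <= weight < stage.hi:
            return stage.label
    raise AssertionError("stage table does not cover the weight axis")  # pragma: no cover


def stage_ration(label: str, table: StageTable = DEFAULT_STAGE_TABLE) -> Ration:
    for stage in table.stages:
        if stage.label == label:
            return stage.ration
    raise KeyError(f"unknown stage '{label}'")


def daily_gain(
    days: Sequence[float], weights: Sequence[float], window_days: float = 14.0
) -> float:
    """Average daily gain (kg/day): OLS slope of weight on time.

    Uses the records inside the trailing ``window_days`` of the latest
    timestamp (all of them if the window holds fewer than two points is an
    error).  Two points reduce to the finite difference.
    """
    d = np.asarray(days, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.size != w.size or d.size < 2 or len(np.unique(d)) < 2:
        raise ValueError("daily gain needs >= 2 records with distinct timestamps")
    keep = d >= d.max() - window_days
    if keep.sum() >= 2 and len(np.unique(d[keep])) >= 2:
        d, w = d[keep], w[keep]
    slope, _ = np.polyfit(d, w, 1)
    return float(slope)


RAPID_GROWTH_BAND = (30.0, 80.0)
SLOW_GAIN_THRESHOLD = 0.6


def adjust_ration(
    stage_ration: Ration,
    weight: float,
    adg: float,
    sbm_band_target: float = 19.0,
) -> Ration:
    """Apply the dynamic feeding rules to a stage ration.

    Slow growers (adg < 0.6 kg/day) get soybean meal at 20% plus 2%
    fishmeal, overriding the rapid-growth rule when both apply; pigs in
    the 30-80 kg band otherwise get corn at 68% and soybean meal at the
    band target.  Untouched ingredients are rescaled pro-rata to keep the
    total at 100%; if rescaling would push a component negative it is
    clamped at zero, the residual absorbed by the largest remaining
    component, and the ration flagged.
    """
    if adg < SLOW_GAIN_THRESHOLD:
        fixed = {"soybean_meal": 20.0, "fishmeal": 2.0}
    elif RAPID_GROWTH_BAND[0] <= weight <= RAPID_GROWTH_BAND[1]:
        fixed = {"corn": 68.0, "soybean_meal": sbm_band_target}
    else:
        return stage_ration

    comps = stage_ration.components()
    free = {k: v for k, v in comps.items() if k not in fixed}
    remainder = 100.0 - sum(fixed.values()) - sum(
        v for k, v in free.items() if k not in ("wheat_bran", "compound_and_other")
    )
    # pro-rata over the filler ingredients only
    filler = {k: free[k] for k in ("wheat_bran", "compound_and_other")}
    filler_total = sum(filler.values())
    clamped = False
    if remainder < 0:
        # fixed targets exceed 100 minus the non-filler components; clamp
        # fillers at zero and absorb the residual into the largest fixed one
        new = {k: 0.0 for k in filler}
        biggest = max(fixed, key=fixed.get)
        fixed = dict(fixed)
        fixed[biggest] += remainder
        clamped = True
    elif filler_total == 0:
        new = {k: 0.0 for k in filler}
        biggest = max(fixed, key=fixed.get)
        fixed = dict(fixed)
        fixed[biggest] += remainder
        clamped = remainder > 0
    else:
        new = {k: remainder * v / filler_total for k, v in filler.items()}
    out = dict(comps)
    out.update(fixed)
    out.update(new)
    return replace(
        stage_ration,
        corn=out["corn"],
        soybean_meal=out["soybean_meal"],
        wheat_bran=out["wheat_bran"],
        compound_and_other=out["compound_and_other"],
        fishmeal=out["fishmeal"],
        rebalance_clamped=clamped,
    )


REFERENCE_ENERGY_MJ_PER_KG = 12.0


def plan_feed_quantity(
    weight: float,
    allowance_table: dict[float, float],
    energy_density: float = REFERENCE_ENERGY_MJ_PER_KG,
) -> float:
    """Daily feed allowance (kg/day) from a piecewise-linear intake curve.

    The allowance table maps live weight (kg) to kg/day of a reference
    12 MJ/kg ration; denser feed scales the mass down proportionally.
    There is no universal intake equation — the curve is a configuration
    input, interpolated linearly and clamped at its end knots.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if not allowance_table:
        raise KeyError("missing feeding allowance table (config key: allowance_table)")
    if energy_density <= 0:
        raise ValueError("energy density must be positive")
    knots = sorted(allowance_table.items())
    xs = np.array([k for k, _ in knots])
    ys = np.array([v for _, v in knots])
    base = float(np.interp(weight, xs, ys))
    return base * REFERENCE_ENERGY_MJ_PER_KG / energy_density
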