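"""Program budgets, relative gain and cost efficiency.

Per-year plot counts and dollar costs for the five scenarios at both program
sizes are shipped as configuration (the published per-year schedules of the
program they describe) rather than derived from cohort sizes, because the
per-category composition behind each printed cost is not fully recoverable;
``itemized_cost`` supports forward costing of user-defined programs from the
unit costs.

Cost efficiency is reported under both circulating conventions: gain per
unit relative cost (relative_gain / relative_cost) and relative cost per
unit gain (relative_cost / relative_gain). The two are exact reciprocals;
reports carry both, each labelled.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "UnitCosts",
    "BudgetSchedule",
    "default_schedule",
    "total_cost",
    "annual_cost",
    "itemized_cost",
    "efficiency",
    "SCHEDULE_TABLE",
]


@dataclasses.dataclass(frozen=True)
class UnitCosts:
    """Dollar unit costs of the program's operations."""

    inbred_plot: float = 12.0
    testcross_plot: float = 8.0
    genotype_sample: float = 10.0
    phenotype_plot: float = 4.0
    dh_line: float = 20.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"unit cost {f.name} must be non-negative")


# (scenario, n_crosses) -> ((year, plots, cost_dollars), ...)
SCHEDULE_TABLE = {
    ("Conv", 50): ((1, 200, 2800), (2, 600, 8800), (3, 1320, 17040),
                   (4, 960, 12320), (5, 475, 5820)),
    ("GSTC", 50): ((1, 200, 2800), (2, 600, 11800), (3, 1320, 29040),
                   (4, 960, 13320), (5, 475, 5970)),
    ("GSF1", 50): ((1, 3400, 62000), (2, 600, 11800), (3, 1320, 29040),
                   (4, 960, 12320), (5, 475, 5820)),
    ("DH", 50): ((1, 50, 25600), (2, 1829, 28348), (3, 960, 12720),
                 (4, 520, 6400)),
    ("DHGS", 50): ((1, 50, 25600), (2, 1829, 40848), (3, 960, 12720),
                   (4, 520, 6400)),
    ("Conv", 200): ((1, 800, 11200), (2, 2400, 35200), (3, 5280, 53760),
                    (4, 3840, 49280), (5, 1900, 23760)),
    ("GSTC", 200): ((1, 800, 11200), (2, 2400, 47200), (3, 5280, 116160),
                    (4, 3840, 53280), (5, 1900, 23880)),
    ("GSF1", 200): ((1, 13600, 248000), (2, 2400, 47200), (3, 5280, 116160),
                    (4, 3840, 49280), (5, 1900, 23280)),
    ("DH", 200): ((1, 200, 102400), (2, 7316, 113392), (3, 3840, 50880),
                  (4, 2080, 25600)),
    ("DHGS", 200): ((1, 200, 102400), (2, 7316, 163392), (3, 3840, 50880),
                    (4, 2080, 25600)),
}


@dataclasses.dataclass(frozen=True)
class BudgetSchedule:
    """Per-year (year, plots, cost) line items for one scenario/size."""

    scenario: str
    n_crosses: int
    rows: tuple  # ((year, plots, cost), ...)

    def __post_init__(self):
        rows = tuple((int(y), int(p), float(c)) for y, p, c in self.rows)
        object.__setattr__(self, "rows", rows)
        years = [r[0] for r in rows]
        if years and years != list(range(1, len(years) + 1)):
            raise ValueError("schedule years must be contiguous from 1")
        if any(p < 0 or c < 0 for _, p, c in rows):
            raise ValueError("plots and costs must be non-negative")

    @property
    def n_years(self) -> int:
        return len(self.rows)


def default_schedule(scenario: str, n_crosses: int) -> BudgetSchedule:
    key = (scenario, int(n_crosses))
    if key not in SCHEDULE_TABLE:
        raise KeyError(f"no shipped schedule for scenario={scenario!r}, "
                       f"n_crosses={n_crosses}")
    return BudgetSchedule(scenario, int(n_crosses), SCHEDULE_TABLE[key])


def total_cost(schedule: BudgetSchedule) -> tuple:
    """(total plots, total dollars), component-wise sums over year rows."""
    plots = sum(r[1] for r in schedule.rows)
    cost = sum(r[2] for r in schedule.rows)
    return plots, cost


def annual_cost(scenario: str, n_crosses: int) -> float:
    """Steady-state yearly spend: with every stage running each year the
    program's annual cost is the sum over the stage-year line items."""
    return total_cost(default_schedule(scenario, n_crosses))[1]


def itemized_cost(counts: Mapping[str, float],
                  costs: UnitCosts = UnitCosts()) -> float:
    """Dot product of per-category counts and unit costs.

    ``counts`` keys must be UnitCosts field names (e.g. inbred_plot,
    genotype_sample); missing categories count as zero.
    """
    valid = {f.name for f in dataclasses.fields(UnitCosts)}
    unknown = set(counts) - valid
    if unknown:
        raise ValueError(f"unknown cost categories: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    return float(sum(v * getattr(costs, k) for k, v in counts.items()))


def efficiency(gains: Mapping[str, float],
               schedules: Mapping[str, BudgetSchedule] | None = None,
               reference: str = "Conv") -> pd.DataFrame:
    """Relative gain, relative cost and both cost-efficiency conventions.

    ``gains`` maps scenario name to its (hybrid) genetic gain; schedules
    default to the shipped 50-cross tables. The reference scenario is
    normalized to 1.00 throughout. A zero reference gain leaves relative
    gains undefined and raises.
    """
    if reference not in gains:
        raise ValueError(f"reference scenario {reference!r} missing")
    if schedules is None:
        schedules = {s: default_schedule(s, 50) for s in gains}
    ref_gain = gains[reference]
    if ref_gain == 0:
        raise ZeroDivisionError("reference gain is zero; efficiency undefined")
    ref_cost = total_cost(schedules[reference])[1]
    rows = []
    for s, g in gains.items():
        plots, cost = total_cost(schedules[s])
        rel_gain = g / ref_gain
        rel_cost = cost / ref_cost
        rows.append(dict(
            scenario=s,
            cycle_years=schedules[s].n_years,
            total_plots=plots,
            total_cost=cost,
            relative_gain=rel_gain,
            relative_cost=rel_cost,
            efficiency_gain_per_cost=rel_gain / rel_cost,
            efficiency_cost_per_gain=rel_cost / rel_gain if rel_gain else
            float("nan"),
        ))
    return pd.DataFrame(rows).set_index("scenario")
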