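"""Monthly projection, payer totals, counterfactual and sensitivity bounds.

A cycle schedule is a step function: each contract-cycle closure fixes the
physician head-count from its effective month until the next closure.  The
projection expands that step function over the horizon month by month (no
discounting, no pro-rating of partial months), accumulates each payer's
costs, and compares them with the counterfactual in which the baseline
(full-program) month repeats over the whole horizon.  The financial impact
per payer is the difference, and one-way fixed-percentage sensitivity
scales it both ways.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from .cost_model import (
    BaselineConvention,
    CostParameters,
    CycleState,
    mh_monthly_cost,
    municipal_monthly_cost,
)
from .errors import DomainError, ValidationError
from .money import brl, round_cents
from .months import Month, month_range


@dataclass(frozen=True)
class CycleEntry:
    label: str
    effective_month: Month
    n_physicians: int


@dataclass(frozen=True)
class CycleSchedule:
    """Ordered contract-cycle closures over an inclusive horizon.

    The first entry is the baseline head-count at the horizon start; counts
    are non-increasing because departures are not replaced.
    """

    entries: tuple[CycleEntry, ...]
    horizon_start: Month
    horizon_end: Month

    def __post_init__(self):
        if not self.entries:
            raise ValidationError("schedule must have at least one entry")
        months = [e.effective_month for e in self.entries]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError("effective months must be strictly increasing")
        if months[0] != self.horizon_start:
            raise ValidationError(
                f"first entry {months[0]} must sit at the horizon start "
                f"{self.horizon_start}"
            )
        if self.horizon_end < self.horizon_start:
            raise ValidationError("horizon end precedes start")
        if any(m > self.horizon_end for m in months):
            raise ValidationError("entry outside horizon")
        counts = [e.n_physicians for e in self.entries]
        if any(c < 0 for c in counts):
            raise ValidationError("physician counts must be non-negative")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError(
                "physician counts must be non-increasing (no replacement)"
            )

    @property
    def n_months(self) -> int:
        return self.horizon_end.index - self.horizon_start.index + 1

    @property
    def n_baseline(self) -> int:
        return self.entries[0].n_physicians

    def month_weights(self) -> list[int]:
        """Months each entry is in force: from its effective month to the
        month before the next entry (the last runs to the horizon end)."""
        bounds = [e.effective_month.index for e in self.entries]
        bounds.append(self.horizon_end.index + 1)
        return [b - a for a, b in zip(bounds, bounds[1:])]

    def count_at(self, month: Month) -> int:
        if not self.horizon_start <= month <= self.horizon_end:
            raise ValidationError(f"month {month} outside horizon")
        count = self.entries[0].n_physicians
        for entry in self.entries:
            if entry.effective_month <= month:
                count = entry.n_physicians
        return count


@dataclass(frozen=True)
class MonthlyRecord:
    month: Month
    n_physicians: int
    mh_cost: Decimal
    municipal_cost: Decimal


@dataclass(frozen=True)
class MonthlyCostSeries:
    records: tuple[MonthlyRecord, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": [str(r.month) for r in self.records],
                "n_physicians": [r.n_physicians for r in self.records],
                "mh_cost": [r.mh_cost for r in self.records],
                "municipal_cost": [r.municipal_cost for r in self.records],
            }
        )


@dataclass(frozen=True)
class ImpactSummary:
    """Payer totals, counterfactual totals and impact magnitudes.

    Impacts are stored as magnitudes with fixed payer directions: the MH
    impact is a saving (counterfactual minus actual), the municipal impact
    an extra burden (actual minus counterfactual).  Published-style signed
    rendering (municipal negative) is the report layer's job.
    """

    mh_total: Decimal
    municipal_total: Decimal
    mh_counterfactual: Decimal
    municipal_counterfactual: Decimal
    mh_impact: Decimal
    municipal_impact: Decimal
    sensitivity_fraction: Optional[Decimal] = None
    mh_bounds: Optional[tuple[Decimal, Decimal]] = None  # (optimistic, pessimistic)
    municipal_bounds: Optional[tuple[Decimal, Decimal]] = None


def expand_schedule(
    schedule: CycleSchedule,
    params: CostParameters,
    convention: BaselineConvention | str = BaselineConvention.AS_PRINTED_TABLE,
) -> MonthlyCostSeries:
    """Materialize the step function month by month.

    Months governed by the first entry are costed with the baseline
    formulas; all later months with the general formulas.  No discounting.
    """
    first_change = (
        schedule.entries[1].effective_month
        if len(schedule.entries) > 1
        else schedule.horizon_end + 1
    )
    records = []
    for month in month_range(schedule.horizon_start, schedule.horizon_end):
        n = schedule.count_at(month)
        state = CycleState(
            n_current=n,
            n_baseline=schedule.n_baseline,
            is_baseline=month < first_change,
        )
        records.append(
            MonthlyRecord(
                month=month,
                n_physicians=n,
                mh_cost=mh_monthly_cost(state, params),
                municipal_cost=municipal_monthly_cost(state, params, convention),
            )
        )
    return MonthlyCostSeries(records=tuple(records))


def totals(series: MonthlyCostSeries) -> tuple[Decimal, Decimal]:
    """(MH, municipal) sums over all months of the series."""
    if not series.records:
        raise ValidationError("cannot total an empty series")
    mh = sum((r.mh_cost for r in series.records), Decimal(0))
    mun = sum((r.municipal_cost for r in series.records), Decimal(0))
    return mh, mun


def counterfactual_totals(
    schedule: CycleSchedule,
    params: CostParameters,
    convention: BaselineConvention | str = BaselineConvention.AS_PRINTED_TABLE,
) -> tuple[Decimal, Decimal]:
    """Payer totals had the baseline head-count persisted all horizon:
    baseline-month costs times the number of horizon months."""
    state = CycleState(
        n_current=schedule.n_baseline,
        n_baseline=schedule.n_baseline,
        is_baseline=True,
    )
    n = schedule.n_months
    return (
        n * mh_monthly_cost(state, params),
        n * municipal_monthly_cost(state, params, convention),
    )


def financial_impact(
    actual: tuple[Decimal, Decimal], counterfactual: tuple[Decimal, Decimal]
) -> ImpactSummary:
    """Scenario-versus-counterfactual impact per payer.

    MH impact = counterfactual - actual (what the ministry stops spending);
    municipal impact = actual - counterfactual (what municipalities must
    newly spend).
    """
    mh_actual, mun_actual = actual
    mh_cf, mun_cf = counterfactual
    return ImpactSummary(
        mh_total=mh_actual,
        municipal_total=mun_actual,
        mh_counterfactual=mh_cf,
        municipal_counterfactual=mun_cf,
        mh_impact=mh_cf - mh_actual,
        municipal_impact=mun_actual - mun_cf,
    )


def sensitivity(summary: ImpactSummary, f: Decimal) -> ImpactSummary:
    """Fixed one-way sensitivity: scale each payer's impact by (1 - f) for
    the optimistic and (1 + f) for the pessimistic bound, to the cent."""
    f = brl(f)
    if not Decimal(0) <= f <= Decimal(1):
        raise DomainError(f"sensitivity fraction {f} outside [0, 1]")
    bound = lambda x: (round_cents(x * (1 - f)), round_cents(x * (1 + f)))
    return ImpactSummary(
        mh_total=summary.mh_total,
        municipal_total=summary.municipal_total,
        mh_counterfactual=summary.mh_counterfactual,
        municipal_counterfactual=summary.municipal_counterfactual,
        mh_impact=summary.mh_impact,
        municipal_impact=summary.municipal_impact,
        sensitivity_fraction=f,
        mh_bounds=bound(summary.mh_impact),
        municipal_bounds=bound(summary.municipal_impact),
    )


def read_schedule(path: str | Path, horizon_end: Month | str) -> CycleSchedule:
    """Read a schedule from delimited text with columns
    label, effective_month (YYYY-MM), n_physicians."""
    df = pd.read_csv(path)
    entries = tuple(
        CycleEntry(
            label=str(row.label),
            effective_month=Month.parse(row.effective_month),
            n_physicians=int(row.n_physicians),
        )
        for row in df.itertuples()
    )
    return CycleSchedule(
        entries=entries,
        horizon_start=entries[0].effective_month,
        horizon_end=Month.parse(horizon_end),
    )


def write_schedule(schedule: CycleSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [e.label for e in schedule.entries],
            "effective_month": [str(e.effective_month) for e in schedule.entries],
            "n_physicians": [e.n_physicians for e in schedule.entries],
        }
    ).to_csv(path, index=False)
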