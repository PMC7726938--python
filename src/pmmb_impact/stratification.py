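"""Municipality stratification: dependence on the program, vulnerability,
replacement eligibility, and the exit projection.

A municipality's *dependence* is the share of its Family Health Strategy
(FHS) teams staffed by a program physician.  Under the 2019 allocation rule
only municipalities in vulnerability profiles at or above a threshold
(default 4) keep physician replacement; elsewhere each physician leaves at
the end of their three-year contract and is not replaced, and a municipality
stays in the program only while it retains at least one physician.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, ValidationError
from .months import Month, month_range

#: dependence bins, percent: half-open [lo, hi) with a closed top bin
DEPENDENCE_BINS: tuple[tuple[int, int], ...] = (
    (0, 20), (20, 40), (40, 60), (60, 80), (80, 100),
)

DEFAULT_ELIGIBILITY_THRESHOLD = 4


def bin_label(bin_: tuple[int, int]) -> str:
    return f"{bin_[0]}-{bin_[1]}"


@dataclass(frozen=True)
class MunicipalityRecord:
    """One municipality's roster state at the horizon start."""

    id: str
    vulnerability_indicator: int
    n_fhs_teams: int
    n_pmmb_physicians: int
    contract_end_months: tuple[Month, ...]

    def __post_init__(self):
        if self.vulnerability_indicator < 1:
            raise ValidationError(
                f"{self.id}: vulnerability indicator must be >= 1"
            )
        if self.n_fhs_teams < 0 or self.n_pmmb_physicians < 0:
            raise ValidationError(f"{self.id}: counts must be non-negative")
        if self.n_pmmb_physicians > self.n_fhs_teams:
            raise ValidationError(
                f"{self.id}: {self.n_pmmb_physicians} physicians exceed "
                f"{self.n_fhs_teams} FHS teams"
            )
        if len(self.contract_end_months) != self.n_pmmb_physicians:
            raise ValidationError(
                f"{self.id}: need one contract-end month per physician"
            )


@dataclass(frozen=True)
class DependenceTable:
    """Dependence-bin x vulnerability-indicator municipality counts."""

    indicators: tuple[int, ...]
    cells: dict[tuple[str, int], int]  # (bin label, indicator) -> count

    @property
    def row_totals(self) -> dict[str, int]:
        return {
            bin_label(b): sum(self.cells[(bin_label(b), i)] for i in self.indicators)
            for b in DEPENDENCE_BINS
        }

    @property
    def column_totals(self) -> dict[int, int]:
        return {
            i: sum(self.cells[(bin_label(b), i)] for b in DEPENDENCE_BINS)
            for i in self.indicators
        }

    @property
    def grand_total(self) -> int:
        return sum(self.cells.values())

    def to_dataframe(self) -> pd.DataFrame:
        """Cross-tab layout: dependence bins as rows, indicators as columns,
        with marginal totals."""
        data = {
            i: [self.cells[(bin_label(b), i)] for b in DEPENDENCE_BINS]
            for i in self.indicators
        }
        df = pd.DataFrame(data, index=[bin_label(b) for b in DEPENDENCE_BINS])
        df.index.name = "dependence_pct"
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        return df


def dependence_percent(m: MunicipalityRecord) -> float:
    """Program physicians as a percentage of the municipality's FHS teams."""
    if m.n_fhs_teams == 0:
        raise DomainError(f"{m.id}: no FHS teams, dependence undefined")
    return 100.0 * m.n_pmmb_physicians / m.n_fhs_teams


def bin_dependence(p: float) -> str:
    """Bin a dependence percentage: [0,20), [20,40), [40,60), [60,80),
    [80,100]."""
    if not 0.0 <= p <= 100.0:
        raise DomainError(f"dependence percent {p} outside [0, 100]")
    for lo, hi in DEPENDENCE_BINS:
        if lo <= p < hi:
            return bin_label((lo, hi))
    return bin_label(DEPENDENCE_BINS[-1])  # p == 100, closed top bin


def cross_tab(
    ms: Sequence[MunicipalityRecord], indicators: Iterable[int] | None = None
) -> DependenceTable:
    """Tally municipalities per (dependence bin, vulnerability indicator)."""
    if indicators is None:
        found = {m.vulnerability_indicator for m in ms}
        indicators = range(1, (max(found) if found else 1) + 1)
    indicators = tuple(indicators)
    cells = {
        (bin_label(b), i): 0 for b in DEPENDENCE_BINS for i in indicators
    }
    for m in ms:
        key = (bin_dependence(dependence_percent(m)), m.vulnerability_indicator)
        if key not in cells:
            raise ValidationError(
                f"{m.id}: indicator {m.vulnerability_indicator} outside "
                f"configured range {indicators}"
            )
        cells[key] += 1
    return DependenceTable(indicators=indicators, cells=cells)


def eligible_for_replacement(
    indicator: int, threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD
) -> bool:
    """2019 rule: only municipalities at or above the vulnerability
    threshold keep physician replacement."""
    if indicator < 1:
        raise DomainError(f"vulnerability indicator {indicator} outside range")
    return indicator >= threshold


@dataclass(frozen=True)
class ExitPoint:
    month: Month
    n_physicians: int
    n_municipalities: int


def exit_projection(
    ms: Sequence[MunicipalityRecord],
    horizon_start: Month | str,
    horizon_end: Month | str,
    threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD,
) -> list[ExitPoint]:
    """Monthly head-counts of physicians and participating municipalities.

    In ineligible municipalities each physician is counted up to the month
    *before* their contract-end month (the vacancy takes effect in the end
    month); eligible municipalities keep their counts throughout because
    departures are replaced.  A municipality participates while it holds at
    least one program physician.
    """
    start, end = Month.parse(horizon_start), Month.parse(horizon_end)
    points = []
    for month in month_range(start, end):
        n_phys = 0
        n_muni = 0
        for m in ms:
            if eligible_for_replacement(m.vulnerability_indicator, threshold):
                count = m.n_pmmb_physicians
            else:
                count = sum(1 for e in m.contract_end_months if e > month)
            n_phys += count
            n_muni += count >= 1
        points.append(ExitPoint(month=month, n_physicians=n_phys,
                                n_municipalities=n_muni))
    return points


def read_roster(path: str | Path) -> list[MunicipalityRecord]:
    """Roster from delimited text: id, vulnerability_indicator, n_fhs_teams,
    n_pmmb_physicians, contract_end_months (semicolon-joined YYYY-MM)."""
    df = pd.read_csv(path, dtype={"contract_end_months": str})
    records = []
    for row in df.itertuples():
        raw = "" if pd.isna(row.contract_end_months) else row.contract_end_months
        ends = tuple(Month.parse(tok) for tok in str(raw).split(";") if tok)
        records.append(
            MunicipalityRecord(
                id=str(row.id),
                vulnerability_indicator=int(row.vulnerability_indicator),
                n_fhs_teams=int(row.n_fhs_teams),
                n_pmmb_physicians=int(row.n_pmmb_physicians),
                contract_end_months=ends,
            )
        )
    return records


def write_roster(ms: Sequence[MunicipalityRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [m.id for m in ms],
            "vulnerability_indicator": [m.vulnerability_indicator for m in ms],
            "n_fhs_teams": [m.n_fhs_teams for m in ms],
            "n_pmmb_physicians": [m.n_pmmb_physicians for m in ms],
            "contract_end_months": [
                ";".join(str(e) for e in m.contract_end_months) for m in ms
            ],
        }
    ).to_csv(path, index=False)
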