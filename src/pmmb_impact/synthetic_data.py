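"""Synthetic municipality rosters and the packaged study fixtures.

The original analysis was assembled from public registries (program
allocation portals and the national health-establishment register).  This
module generates rosters with the same statistical structure — municipality
counts per (dependence bin x vulnerability indicator) cell, a statewide
physician total, and a contract-end-month profile — so the whole pipeline is
testable without any download.  ``paper_fixture`` packages the published
marginals: 2,533 physicians across 373 municipalities, the published
dependence-by-vulnerability cross-tab, and the ten contract-cycle closures
from January 2019 to March 2022.

Generation is deterministic given the seed: exact quota allocation first,
seeded assignment of the residual degrees of freedom second.  Per-
municipality physician counts are *not* published, so the fixture roster is
one frozen member of the admissible set — any roster consistent with the
published marginals would do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import payroll
from .cost_model import CostParameters, default_parameters
from .errors import InfeasibleSpecError, ValidationError
from .months import Month
from .projection import CycleEntry, CycleSchedule
from .stratification import (
    DEPENDENCE_BINS,
    DEFAULT_ELIGIBILITY_THRESHOLD,
    MunicipalityRecord,
    bin_label,
    eligible_for_replacement,
)

#: published contract-cycle closures: (label, effective month, head-count).
#: The duplicated "11th cycle" row of the source table is the 14th cycle,
#: effective June 2020 (the only reading under which the totals close).
FIXTURE_CYCLES: tuple[tuple[str, str, int], ...] = (
    ("MDP ceiling", "2019-01", 2533),
    ("9th cycle", "2019-03", 2165),
    ("10th cycle", "2019-04", 2107),
    ("11th cycle", "2019-06", 2106),
    ("12th cycle", "2019-08", 2084),
    ("13th cycle", "2020-02", 1909),
    ("14th cycle", "2020-06", 1484),
    ("15th cycle", "2021-01", 1427),
    ("16th cycle", "2021-12", 546),
    ("17th cycle", "2022-03", 320),
)

FIXTURE_HORIZON: tuple[str, str] = ("2019-01", "2022-03")

#: published municipality counts per dependence bin (rows) and
#: vulnerability indicator 1..6 (columns); grand total 373.
FIXTURE_CROSS_TAB: dict[str, tuple[int, ...]] = {
    "0-20": (53, 39, 26, 7, 1, 1),
    "20-40": (27, 50, 17, 11, 4, 6),
    "40-60": (16, 36, 5, 25, 0, 7),
    "60-80": (0, 6, 3, 2, 0, 1),
    "80-100": (1, 8, 0, 16, 0, 5),
}

FIXTURE_SEED = 20190131


@dataclass(frozen=True)
class RosterSpec:
    """Constraints a generated roster must satisfy exactly."""

    n_municipalities: int
    total_physicians: int
    indicator_marginals: dict[int, int] = field(default_factory=dict)
    dependence_marginals: dict[str, int] = field(default_factory=dict)
    #: exact cells: bin label -> municipality count per indicator 1..k
    cross_tab_cells: Optional[dict[str, tuple[int, ...]]] = None
    #: contract-end profile for ineligible-municipality physicians:
    #: month -> departure count (D14 back-solve input)
    contract_end_profile: Optional[dict[str, int]] = None
    eligibility_threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD
    default_end_month: str = "2022-03"
    attrition_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.attrition_rate <= 1.0:
            raise ValidationError("attrition_rate must lie in [0, 1]")


# smallest physician count whose ratio can land in each bin (60-80% needs
# two physicians: 100*1/t never falls in [60, 80) for integer t)
_MIN_PHYSICIANS = {"0-20": 1, "20-40": 1, "40-60": 1, "60-80": 2, "80-100": 1}


def _teams_for(p: int, bin_: tuple[int, int]) -> int:
    """Smallest team count placing p physicians inside the dependence bin."""
    lo, hi = bin_
    top = bin_ == DEPENDENCE_BINS[-1]
    for t in range(p, 6 * p + 2):
        if t == 0:
            continue
        ratio = 100.0 * p / t
        if (lo <= ratio <= hi) if top else (lo <= ratio < hi):
            return t
    raise InfeasibleSpecError(
        f"no team count places {p} physicians in dependence bin {bin_}"
    )


def _resolve_cells(spec: RosterSpec) -> dict[str, tuple[int, ...]]:
    """Exact (bin, indicator) municipality counts from the spec.

    Explicit cells win; otherwise the two marginals are combined by the
    northwest-corner rule (deterministic, matches both marginals exactly).
    """
    if spec.cross_tab_cells is not None:
        cells = {b: tuple(v) for b, v in spec.cross_tab_cells.items()}
        if set(cells) != {bin_label(b) for b in DEPENDENCE_BINS}:
            raise InfeasibleSpecError(
                "cross_tab_cells must cover exactly the five dependence bins"
            )
        total = sum(sum(v) for v in cells.values())
        if total != spec.n_municipalities:
            raise InfeasibleSpecError(
                f"cells sum to {total}, spec says {spec.n_municipalities} "
                "municipalities"
            )
        if spec.indicator_marginals:
            k = len(next(iter(cells.values())))
            for i in range(1, k + 1):
                col = sum(cells[bin_label(b)][i - 1] for b in DEPENDENCE_BINS)
                want = spec.indicator_marginals.get(i, 0)
                if col != want:
                    raise InfeasibleSpecError(
                        f"indicator {i} column sums to {col}, marginal says {want}"
                    )
        return cells

    if not spec.indicator_marginals:
        raise InfeasibleSpecError(
            "need cross_tab_cells or indicator_marginals to place municipalities"
        )
    if sum(spec.indicator_marginals.values()) != spec.n_municipalities:
        raise InfeasibleSpecError(
            "indicator_marginals must sum to n_municipalities"
        )
    dep = spec.dependence_marginals or {
        bin_label(DEPENDENCE_BINS[2]): spec.n_municipalities
    }
    if sum(dep.values()) != spec.n_municipalities:
        raise InfeasibleSpecError(
            "dependence_marginals must sum to n_municipalities"
        )
    indicators = sorted(spec.indicator_marginals)
    # northwest-corner: walk bins x indicators, draining both marginals
    remaining_col = dict(spec.indicator_marginals)
    cells = {}
    for b in DEPENDENCE_BINS:
        row = dep.get(bin_label(b), 0)
        counts = []
        for i in indicators:
            take = min(row, remaining_col[i])
            counts.append(take)
            row -= take
            remaining_col[i] -= take
        cells[bin_label(b)] = tuple(counts)
    return cells


def generate_roster(spec: RosterSpec) -> list[MunicipalityRecord]:
    """Generate a roster satisfying ``spec`` exactly; deterministic per seed.

    Municipalities are laid out cell by cell; each starts at the minimum
    physician count its bin admits, and the remaining physicians are dealt
    out by the seeded generator (within the eligibility groups when a
    contract-end profile pins the ineligible total).  Team counts are chosen
    as the smallest count keeping the municipality inside its bin.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _resolve_cells(spec)
    bins_by_label = {bin_label(b): b for b in DEPENDENCE_BINS}

    munis: list[dict] = []
    for b in DEPENDENCE_BINS:
        lbl = bin_label(b)
        for ind, count in enumerate(cells[lbl], start=1):
            for _ in range(count):
                munis.append(
                    {
                        "bin": lbl,
                        "indicator": ind,
                        "p": _MIN_PHYSICIANS[lbl],
                        "eligible": eligible_for_replacement(
                            ind, spec.eligibility_threshold
                        ),
                    }
                )
    for idx, m in enumerate(munis):
        m["id"] = f"SP-{idx + 1:03d}"

    base_total = sum(m["p"] for m in munis)
    extra = spec.total_physicians - base_total
    if extra < 0:
        raise InfeasibleSpecError(
            f"total_physicians={spec.total_physicians} below the minimum "
            f"{base_total} needed to give every municipality a feasible count"
        )

    if spec.contract_end_profile is not None:
        inelig_target = sum(spec.contract_end_profile.values())
        groups = [
            ([m for m in munis if not m["eligible"]], inelig_target),
            ([m for m in munis if m["eligible"]],
             spec.total_physicians - inelig_target),
        ]
    else:
        groups = [(munis, spec.total_physicians)]

    for members, target in groups:
        base = sum(m["p"] for m in members)
        if target < base:
            raise InfeasibleSpecError(
                f"group target {target} physicians below its minimum {base}"
            )
        if members:
            for pick in rng.integers(0, len(members), size=target - base):
                members[pick]["p"] += 1
        elif target:
            raise InfeasibleSpecError(
                f"{target} physicians assigned to an empty eligibility group"
            )

    # contract-end months: profile months go to ineligible physicians
    # (seeded order); everyone else ends at the default month
    default_end = Month.parse(spec.default_end_month)
    for m in munis:
        m["ends"] = [default_end] * m["p"]
    if spec.contract_end_profile:
        slots = [
            (mi, k)
            for mi, m in enumerate(munis)
            if not m["eligible"]
            for k in range(m["p"])
        ]
        slots = [slots[i] for i in rng.permutation(len(slots))]
        cursor = 0
        for month_str in sorted(spec.contract_end_profile):
            month = Month.parse(month_str)
            for _ in range(spec.contract_end_profile[month_str]):
                mi, k = slots[cursor]
                munis[mi]["ends"][k] = month
                cursor += 1

    records = []
    for m in munis:
        records.append(
            MunicipalityRecord(
                id=m["id"],
                vulnerability_indicator=m["indicator"],
                n_fhs_teams=_teams_for(m["p"], bins_by_label[m["bin"]]),
                n_pmmb_physicians=m["p"],
                contract_end_months=tuple(sorted(m["ends"])),
            )
        )
    return records


def fixture_schedule() -> CycleSchedule:
    """The published ten-entry cycle schedule over Jan/2019-Mar/2022."""
    return CycleSchedule(
        entries=tuple(
            CycleEntry(label=lbl, effective_month=Month.parse(mo), n_physicians=n)
            for lbl, mo, n in FIXTURE_CYCLES
        ),
        horizon_start=Month.parse(FIXTURE_HORIZON[0]),
        horizon_end=Month.parse(FIXTURE_HORIZON[1]),
    )


def fixture_departure_profile() -> dict[str, int]:
    """Departure counts per cycle month: successive head-count drops of the
    published schedule (these physicians sit in ineligible municipalities)."""
    counts = [n for _, _, n in FIXTURE_CYCLES]
    months = [mo for _, mo, _ in FIXTURE_CYCLES]
    return {
        months[i]: counts[i - 1] - counts[i]
        for i in range(1, len(counts))
        if counts[i - 1] > counts[i]
    }


def fixture_roster_spec(seed: int = FIXTURE_SEED) -> RosterSpec:
    cells = FIXTURE_CROSS_TAB
    marginals = {
        i + 1: sum(cells[bin_label(b)][i] for b in DEPENDENCE_BINS)
        for i in range(6)
    }
    return RosterSpec(
        n_municipalities=373,
        total_physicians=2533,
        indicator_marginals=marginals,
        cross_tab_cells=cells,
        contract_end_profile=fixture_departure_profile(),
        seed=seed,
    )


def paper_fixture(
    seed: int = FIXTURE_SEED,
) -> tuple[CycleSchedule, list[MunicipalityRecord], CostParameters,
           payroll.PayrollRules]:
    """The packaged study conditions: cycle schedule, a roster consistent
    with the published marginals, cost parameters and payroll rules."""
    return (
        fixture_schedule(),
        generate_roster(fixture_roster_spec(seed)),
        default_parameters(),
        payroll.default_rules(),
    )


def apply_attrition(
    schedule: CycleSchedule, rate: float, seed: int = 0
) -> CycleSchedule:
    """Exploratory scenario: stochastic first-year contract drop-out.

    Draws binomial extra departures from the cohort present at the horizon
    start and applies them at the end of the first year, clamping later
    entries so counts stay non-increasing.  Rate 0 returns the schedule
    unchanged; the headline analysis never applies attrition (the study's
    fixed-effect assumption).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"attrition rate {rate} outside [0, 1]")
    if rate == 0.0:
        return schedule
    rng = np.random.default_rng(seed)
    cohort = schedule.n_baseline
    departures = int(rng.binomial(cohort, rate))
    hit_month = schedule.horizon_start + 12
    entries: list[CycleEntry] = []
    cap = None
    inserted = False

    def clamp(n: int) -> int:
        return n if cap is None else min(n, cap)

    for entry in schedule.entries:
        if not inserted and entry.effective_month >= hit_month:
            prior = entries[-1].n_physicians if entries else cohort
            cap = max(0, prior - departures)
            inserted = True
            if entry.effective_month > hit_month and hit_month <= schedule.horizon_end:
                entries.append(
                    CycleEntry("first-year attrition", hit_month, cap)
                )
        entries.append(
            CycleEntry(entry.label, entry.effective_month,
                       clamp(entry.n_physicians))
        )
    if not inserted and hit_month <= schedule.horizon_end:
        prior = entries[-1].n_physicians
        entries.append(
            CycleEntry("first-year attrition", hit_month,
                       max(0, prior - departures))
        )
    return CycleSchedule(
        entries=tuple(entries),
        horizon_start=schedule.horizon_start,
        horizon_end=schedule.horizon_end,
    )
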