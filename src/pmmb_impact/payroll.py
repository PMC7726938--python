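"""Celetist (CLT) payroll arithmetic for a replacement physician hire.

The municipalities that lose a PMMB physician are assumed to hire a
substitute under Brazil's consolidated labor law at a *net* wage equal to the
program scholarship.  This module converts between gross and net wages under
the 2019 employee social-security (INSS) band schedule and the 2019 monthly
income-tax (IRRF) bracket table, and assembles the monthly and annual cost
borne by the employer (INSS employer quota, FGTS severance deposits, paid
vacation plus the statutory one-third bonus, and the 13th salary).

Tax/contribution schedules are configuration, not code: the packaged 2019
defaults reproduce the published figures but any vintage can be supplied.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import DomainError, NumericalError
from .money import brl, round_cents

#: labels accepted in ``PayrollRules.annual_composition``
ANNUAL_COMPONENTS = (
    "vacation_bonus",            # one month of vacation pay + 1/3 bonus
    "employer_quota_vacation",   # INSS employer quota on the vacation bonus
    "thirteenth_salary",
    "fgts_thirteenth",
    "employer_quota_thirteenth",
    "notice",                    # termination notice month
    "employer_quota_notice",
    "fgts_notice",
)


class ContributionBand(BaseModel):
    """One band of the employee INSS schedule.

    The schedule is *flat-band*: the rate of the band containing the gross
    applies to the whole gross (pre-2020 Brazilian rule), with a flat cap
    above the contribution ceiling.
    """

    model_config = ConfigDict(frozen=True)

    upper: Optional[Decimal] = None  # None = unbounded
    rate: Decimal

    @field_validator("upper", mode="before")
    @classmethod
    def _brl(cls, v):
        return None if v is None else brl(v)

    @field_validator("rate", mode="before")
    @classmethod
    def _dec(cls, v):
        return Decimal(str(v))

    @field_validator("rate")
    @classmethod
    def _rate_range(cls, v):
        if not Decimal(0) <= v <= Decimal(1):
            raise ValueError("contribution rate must lie in [0, 1]")
        return v


class TaxBracket(BaseModel):
    """Progressive income-tax bracket in marginal-rate/deduction-parcel form:
    tax = taxable * rate - deduction for the bracket containing the taxable
    amount (continuous across boundaries by construction of the parcels)."""

    model_config = ConfigDict(frozen=True)

    upper: Optional[Decimal] = None  # None = unbounded (last bracket only)
    rate: Decimal
    deduction: Decimal = Decimal("0")

    @field_validator("upper", "deduction", mode="before")
    @classmethod
    def _brl(cls, v):
        return None if v is None else brl(v)

    @field_validator("rate", mode="before")
    @classmethod
    def _dec(cls, v):
        return Decimal(str(v))

    @field_validator("rate")
    @classmethod
    def _rate_range(cls, v):
        if not Decimal(0) <= v <= Decimal(1):
            raise ValueError("tax rate must lie in [0, 1]")
        return v

    @field_validator("deduction")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("deduction parcel must be non-negative")
        return v


class PayrollRules(BaseModel):
    model_config = ConfigDict(frozen=True)

    contribution_bands: Sequence[ContributionBand]
    employee_contribution_cap: Optional[Decimal] = None
    tax_brackets: Sequence[TaxBracket]
    employer_quota_rate: Decimal
    severance_fund_rate: Decimal
    vacation_bonus_factor: Decimal = Decimal(1) / Decimal(3)
    months_per_year: int = 12
    include_13th: bool = True
    annual_composition: Sequence[str] = (
        "vacation_bonus",
        "employer_quota_vacation",
        "thirteenth_salary",
        "fgts_thirteenth",
    )

    @field_validator("employee_contribution_cap", mode="before")
    @classmethod
    def _brl(cls, v):
        return None if v is None else brl(v)

    @field_validator(
        "employer_quota_rate",
        "severance_fund_rate",
        "vacation_bonus_factor",
        mode="before",
    )
    @classmethod
    def _dec(cls, v):
        return Decimal(str(v))

    @field_validator("employer_quota_rate", "severance_fund_rate")
    @classmethod
    def _rate_range(cls, v):
        if not Decimal(0) <= v <= Decimal(1):
            raise ValueError("rate must lie in [0, 1]")
        return v

    @field_validator("annual_composition")
    @classmethod
    def _known_labels(cls, v):
        unknown = set(v) - set(ANNUAL_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown annual components: {sorted(unknown)}")
        return tuple(v)

    @model_validator(mode="after")
    def _ordered_schedules(self):
        for seq, what in ((self.contribution_bands, "contribution bands"),
                          (self.tax_brackets, "tax brackets")):
            bounded = [b.upper for b in seq if b.upper is not None]
            if any(b.upper is None for b in seq[:-1]):
                raise ValueError(f"only the last of the {what} may be unbounded")
            if any(hi <= lo for lo, hi in zip(bounded, bounded[1:])):
                raise ValueError(f"{what} must have strictly increasing upper bounds")
        if not self.tax_brackets or self.tax_brackets[-1].upper is not None:
            raise ValueError("the last tax bracket must be unbounded")
        return self


class PayrollBreakdown(BaseModel):
    """Gross-to-net decomposition plus employer-side totals.

    ``monthly_employer_total`` is kept at full precision (gross x (1 + quota
    + FGTS) is exact in decimal); ``component_map`` carries the cent-rounded
    figures for display.
    """

    model_config = ConfigDict(frozen=True)

    gross: Decimal
    employee_contribution: Decimal
    income_tax: Decimal
    net: Decimal
    monthly_employer_total: Decimal
    annual_employer_total: Decimal
    component_map: dict[str, Decimal]


def default_rules() -> PayrollRules:
    """The packaged 2019 schedules.

    Employee INSS: 8/9/11% flat bands with ceiling 5,839.45 (cap
    0.11 x 5,839.45 = 642.34); IRRF monthly table with top bracket 27.5%
    and deduction parcel 869.36; employer quota 20%, FGTS 8%.
    """
    return PayrollRules(
        contribution_bands=[
            ContributionBand(upper="1751.81", rate="0.08"),
            ContributionBand(upper="2919.72", rate="0.09"),
            ContributionBand(upper="5839.45", rate="0.11"),
        ],
        employee_contribution_cap="642.34",
        tax_brackets=[
            TaxBracket(upper="1903.98", rate="0"),
            TaxBracket(upper="2826.65", rate="0.075", deduction="142.80"),
            TaxBracket(upper="3751.05", rate="0.15", deduction="354.80"),
            TaxBracket(upper="4664.68", rate="0.225", deduction="636.13"),
            TaxBracket(upper=None, rate="0.275", deduction="869.36"),
        ],
        employer_quota_rate="0.20",
        severance_fund_rate="0.08",
    )


def employee_contribution(gross: Decimal, rules: PayrollRules) -> Decimal:
    """Employee INSS deduction for ``gross``, capped at the ceiling value."""
    gross = brl(gross)
    if gross < 0:
        raise DomainError("gross wage must be non-negative")
    value = None
    for band in rules.contribution_bands:
        if band.upper is None or gross <= band.upper:
            value = round_cents(gross * band.rate)
            break
    if value is None:
        # above the top bounded band: the flat cap applies
        if rules.employee_contribution_cap is None:
            raise DomainError(
                "gross exceeds all contribution bands and no cap is configured"
            )
        return rules.employee_contribution_cap
    if rules.employee_contribution_cap is not None:
        value = min(value, rules.employee_contribution_cap)
    return value


def income_tax(taxable: Decimal, rules: PayrollRules) -> Decimal:
    """Monthly withholding tax on ``taxable`` (gross minus INSS)."""
    taxable = brl(taxable)
    if taxable < 0:
        raise DomainError("taxable amount must be non-negative")
    for bracket in rules.tax_brackets:
        if bracket.upper is None or taxable <= bracket.upper:
            tax = taxable * bracket.rate - bracket.deduction
            return round_cents(max(tax, Decimal(0)))
    raise AssertionError("unreachable: last bracket is unbounded")


def net_from_gross(gross: Decimal, rules: PayrollRules) -> PayrollBreakdown:
    """Full payroll breakdown for a gross monthly wage.

    Monthly employer total is gross x (1 + employer quota + FGTS).  The
    annual total is assembled from ``rules.annual_composition`` on top of
    ``months_per_year`` monthly totals, accumulated at full precision and
    rounded once at the end (the convention that reproduces published
    spreadsheet totals).
    """
    gross = brl(gross)
    if gross < 0:
        raise DomainError("gross wage must be non-negative")
    contribution = employee_contribution(gross, rules)
    tax = income_tax(gross - contribution, rules)
    net = gross - contribution - tax

    quota = gross * rules.employer_quota_rate
    fgts = gross * rules.severance_fund_rate
    monthly_total = gross + quota + fgts

    vacation_bonus = gross * (1 + rules.vacation_bonus_factor)
    thirteenth = gross if rules.include_13th else Decimal(0)
    components: dict[str, Decimal] = {
        "vacation_bonus": vacation_bonus,
        "employer_quota_vacation": vacation_bonus * rules.employer_quota_rate,
        "thirteenth_salary": thirteenth,
        "fgts_thirteenth": thirteenth * rules.severance_fund_rate,
        "employer_quota_thirteenth": thirteenth * rules.employer_quota_rate,
        "notice": gross,
        "employer_quota_notice": gross * rules.employer_quota_rate,
        "fgts_notice": gross * rules.severance_fund_rate,
    }
    annual = rules.months_per_year * monthly_total + sum(
        (components[label] for label in rules.annual_composition), Decimal(0)
    )

    component_map = {
        "employee_contribution": contribution,
        "income_tax": tax,
        "employer_quota": round_cents(quota),
        "severance_fund": round_cents(fgts),
    }
    component_map.update({k: round_cents(v) for k, v in components.items()})

    return PayrollBreakdown(
        gross=gross,
        employee_contribution=contribution,
        income_tax=tax,
        net=net,
        monthly_employer_total=monthly_total,
        annual_employer_total=round_cents(annual),
        component_map=component_map,
    )


def gross_from_net(
    net_target: Decimal, rules: PayrollRules, max_iter: int = 200
) -> Decimal:
    """Invert the gross-to-net map: the whole-cent gross that best
    reproduces ``net_target`` (within 0.01; ties broken toward the smaller
    gross).

    Uses per-bracket linear inversion (assume the top contribution regime
    and each tax bracket in turn, solve the linear equation, verify) with a
    cent-grid bisection fallback; raises :class:`NumericalError` if no gross
    reproduces the target net to the cent tolerance.
    """
    net_target = brl(net_target)
    if net_target < 0:
        raise DomainError("net wage must be non-negative")
    if net_target == 0:
        return Decimal("0.00")

    def net_of(g: Decimal) -> Decimal:
        return net_from_gross(g, rules).net

    # linear inversion: within one (band, bracket) cell the map is
    # net = g - c(g) - (g - c(g)) * rate + deduction with c(g) affine in g
    candidates: list[Decimal] = []
    band_specs: list[tuple[Decimal, Decimal]] = [
        (band.rate, Decimal(0)) for band in rules.contribution_bands
    ]
    if rules.employee_contribution_cap is not None:
        band_specs.append((Decimal(0), rules.employee_contribution_cap))
    for c_rate, c_flat in band_specs:
        for bracket in rules.tax_brackets:
            slope = (1 - c_rate) * (1 - bracket.rate)
            if slope <= 0:
                continue
            g = (net_target - bracket.deduction + c_flat * (1 - bracket.rate)) / slope
            candidates.append(round_cents(g))
    tol = Decimal("0.01")
    hits = []
    for g in candidates:
        if g < 0:
            continue
        for probe in (g - Decimal("0.01"), g, g + Decimal("0.01")):
            if probe >= 0:
                err = abs(net_of(probe) - net_target)
                if err <= tol:
                    hits.append((err, probe))
    if hits:
        # exact reproduction preferred; ties broken toward the smaller gross
        return min(hits)[1]

    # bisection fallback on the cent grid (net is monotone within regimes;
    # bracket the target by doubling)
    lo, hi = Decimal("0.00"), max(net_target * 2, Decimal("1.00"))
    for _ in range(max_iter):
        if net_of(hi) >= net_target:
            break
        hi *= 2
    else:
        raise NumericalError("gross_from_net failed to bracket the target net")
    for _ in range(max_iter):
        mid = round_cents((lo + hi) / 2)
        if mid in (lo, hi):
            break
        if net_of(mid) < net_target:
            lo = mid
        else:
            hi = mid
    for g in (lo, hi):
        if abs(net_of(g) - net_target) <= tol:
            return g
    raise NumericalError(
        f"gross_from_net did not converge to net {net_target} within 0.01"
    )
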