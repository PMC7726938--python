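"""Per-cycle monthly costs for the two payers.

The program's cost structure, per physician-month:

* The Ministry of Health (MH) pays each PMMB physician's scholarship, keeps
  the reduced variable Primary Care Floor (PCF) transfer for teams staffed by
  a program physician, pays the difference back up to the full PCF for every
  vacated slot, and funds a fixed set of supervision references.
* Municipalities pay food and housing aid for each program physician; for
  every physician lost without program replacement they pay a celetist
  substitute's full employer cost, offset by the restored full PCF transfer.

Counts enter as whole physicians; parameters are exact decimals, so every
cycle cost here is exact.
"""

from __future__ import annotations

import enum
from decimal import Decimal
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import payroll
from .errors import ConfigError
from .money import brl


class BaselineConvention(str, enum.Enum):
    """How the baseline (full-program) month is booked for municipalities.

    ``as_printed_table``: food aid is the cash outlay and the reduced PCF
    transfer a receipt, giving the published net receipt of
    n x (food - pcf_pmmb); rent is treated as non-cash.  ``as_printed_box``
    books n x (food + rent + pcf_pmmb) as a cost, the literal formula
    statement, which does not match the published baseline row.
    """

    AS_PRINTED_TABLE = "as_printed_table"
    AS_PRINTED_BOX = "as_printed_box"


class CostParameters(BaseModel):
    """Monetary parameters of the budget-impact model (all BRL/month).

    ``physician_wage_monthly`` defaults to the payroll-derived employer cost
    of a substitute hired at a net wage equal to the scholarship, kept at
    full precision (20,236.2496 = 15,809.57 x 1.28); published tables round
    it to 20,236.25 for display but their cost cells use the exact value.
    """

    model_config = ConfigDict(frozen=True)

    scholarship: Decimal = Decimal("11865.60")
    pcf_full: Decimal = Decimal("7130.00")
    pcf_pmmb: Decimal = Decimal("4000.00")
    pcf_dif: Optional[Decimal] = None  # derived: pcf_full - pcf_pmmb
    ref_central: Decimal = Decimal("6500.00")
    ref_decentralized: Decimal = Decimal("6000.00")
    n_decentralized: int = 7
    rent: Decimal = Decimal("2000.00")
    food: Decimal = Decimal("600.00")
    physician_wage_monthly: Decimal = Decimal("20236.2496")
    sensitivity_fraction: Decimal = Decimal("0.30")

    @field_validator(
        "scholarship", "pcf_full", "pcf_pmmb", "pcf_dif", "ref_central",
        "ref_decentralized", "rent", "food", "physician_wage_monthly",
        mode="before",
    )
    @classmethod
    def _brl(cls, v):
        return None if v is None else brl(v)

    @field_validator("sensitivity_fraction", mode="before")
    @classmethod
    def _dec(cls, v):
        return Decimal(str(v))

    @model_validator(mode="after")
    def _consistency(self):
        derived = self.pcf_full - self.pcf_pmmb
        if self.pcf_dif is None:
            object.__setattr__(self, "pcf_dif", derived)
        elif self.pcf_dif != derived:
            raise ValueError(
                f"pcf_dif={self.pcf_dif} must equal pcf_full - pcf_pmmb = {derived}"
            )
        for name in ("scholarship", "pcf_full", "pcf_pmmb", "ref_central",
                     "ref_decentralized", "rent", "food",
                     "physician_wage_monthly"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not Decimal(0) <= self.sensitivity_fraction <= Decimal(1):
            raise ValueError("sensitivity_fraction must lie in [0, 1]")
        if self.n_decentralized < 0:
            raise ValueError("n_decentralized must be non-negative")
        return self


class CycleState(BaseModel):
    """Physician head-count of one contract cycle against the program
    ceiling (the January/2019 roster)."""

    model_config = ConfigDict(frozen=True)

    n_current: int
    n_baseline: int
    is_baseline: bool = False

    @model_validator(mode="after")
    def _bounds(self):
        if not 0 <= self.n_current <= self.n_baseline:
            raise ValueError("require 0 <= n_current <= n_baseline")
        if self.is_baseline and self.n_current != self.n_baseline:
            raise ValueError("a baseline state must carry the full head-count")
        return self


def default_parameters(from_payroll: bool = True) -> CostParameters:
    """Packaged parameter set.

    With ``from_payroll`` (default) the replacement wage is recomputed live
    by grossing up the scholarship under the default payroll rules; the
    result equals the packaged constant (checked in tests).
    """
    if not from_payroll:
        return CostParameters()
    wage = replacement_wage_from_payroll(
        Decimal("11865.60"), payroll.default_rules()
    )
    return CostParameters(physician_wage_monthly=wage)


def replacement_wage_from_payroll(
    scholarship_net: Decimal, rules: payroll.PayrollRules
) -> Decimal:
    """Monthly employer cost of a substitute hired at a net wage equal to
    the scholarship: gross-up then apply employer charges (full precision)."""
    gross = payroll.gross_from_net(scholarship_net, rules)
    return payroll.net_from_gross(gross, rules).monthly_employer_total


def references_total(params: CostParameters) -> Decimal:
    """Monthly spend on supervision references: one central plus the
    decentralized state references."""
    return params.ref_central + params.n_decentralized * params.ref_decentralized


def mh_monthly_cost(state: CycleState, params: CostParameters) -> Decimal:
    """Ministry of Health monthly cost for a cycle state.

    Ref + n_current x (scholarship + PCF_pmmb) + (n_baseline - n_current)
    x PCF_dif.  At the baseline (n_current = n_baseline) this reduces to the
    full-program expression Ref + n x (scholarship + PCF_pmmb).
    """
    departed = state.n_baseline - state.n_current
    return (
        references_total(params)
        + state.n_current * (params.scholarship + params.pcf_pmmb)
        + departed * params.pcf_dif
    )


def municipal_monthly_cost(
    state: CycleState,
    params: CostParameters,
    convention: BaselineConvention | str = BaselineConvention.AS_PRINTED_TABLE,
) -> Decimal:
    """Municipal monthly cost (positive = net outlay) for a cycle state.

    Non-baseline months: n_current x (food + rent) + departed x wage
    - departed x (PCF_pmmb + PCF_dif), i.e. aid for remaining program
    physicians plus substitute payroll net of the restored full PCF.
    Baseline months follow ``convention`` (see :class:`BaselineConvention`).
    """
    try:
        convention = BaselineConvention(convention)
    except ValueError as exc:
        raise ConfigError(f"unknown baseline convention {convention!r}") from exc
    if state.is_baseline:
        if convention is BaselineConvention.AS_PRINTED_TABLE:
            return state.n_baseline * (params.food - params.pcf_pmmb)
        return state.n_baseline * (params.food + params.rent + params.pcf_pmmb)
    departed = state.n_baseline - state.n_current
    return (
        state.n_current * (params.food + params.rent)
        + departed * params.physician_wage_monthly
        - departed * (params.pcf_pmmb + params.pcf_dif)
    )
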