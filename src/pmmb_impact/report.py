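"""End-to-end pipeline: expand, accumulate, stratify, render, log.

``run_pipeline`` ties the stages together and writes every table both as
RFC-4180 delimited text and as JSON, plus a structured run log recording the
parameters used and one audit entry per computed cell.  Machine outputs are
always plain ISO-decimal; the human-readable rendering (cents, thousands
separators, Brazilian or ISO locale) is applied only in formatted columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cost_model import (
    BaselineConvention,
    CostParameters,
    CycleState,
    mh_monthly_cost,
    municipal_monthly_cost,
)
from .errors import ConfigError
from .money import fmt_brl, round_cents
from .payroll import PayrollRules, default_rules
from .projection import (
    CycleSchedule,
    counterfactual_totals,
    expand_schedule,
    financial_impact,
    sensitivity,
    totals,
)
from .stratification import (
    DEFAULT_ELIGIBILITY_THRESHOLD,
    MunicipalityRecord,
    cross_tab,
    exit_projection,
)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on, resolved in memory."""

    params: CostParameters
    payroll_rules: PayrollRules
    schedule: CycleSchedule
    roster: Optional[Sequence[MunicipalityRecord]] = None
    convention: BaselineConvention = BaselineConvention.AS_PRINTED_TABLE
    eligibility_threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD
    sensitivity_fraction: Optional[Decimal] = None  # None -> params value
    out_dir: Optional[Path] = None
    locale: str = "iso"
    seed: int = 0


@dataclass
class ReportBundle:
    per_cycle: pd.DataFrame
    impact: dict
    dependence: Optional[pd.DataFrame]
    exit_series: Optional[pd.DataFrame]
    audit_log: list[dict]
    paths: dict[str, Path] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    audit: list[dict] = []

    def log(cell: str, formula: str, value) -> None:
        audit.append({"cell": cell, "formula": formula, "value": str(value)})

    # --- per-cycle cost table -------------------------------------------
    schedule, params = cfg.schedule, cfg.params
    weights = schedule.month_weights()
    rows = []
    for entry, weight in zip(schedule.entries, weights):
        state = CycleState(
            n_current=entry.n_physicians,
            n_baseline=schedule.n_baseline,
            is_baseline=entry is schedule.entries[0],
        )
        mh = mh_monthly_cost(state, params)
        mun = municipal_monthly_cost(state, params, cfg.convention)
        log(f"mh[{entry.label}]",
            "ref + n*(scholarship+pcf_pmmb) + departed*pcf_dif", mh)
        log(f"municipal[{entry.label}]",
            "baseline: n*(food-pcf_pmmb); else n*(food+rent) "
            "+ departed*(wage-pcf_full)", mun)
        rows.append(
            {
                "cycle": entry.label,
                "effective_month": str(entry.effective_month),
                "months_in_force": weight,
                "n_physicians": entry.n_physicians,
                "mh_cost": mh,
                "municipal_cost": mun,
                "mh_cost_fmt": fmt_brl(mh, cfg.locale),
                "municipal_cost_fmt": fmt_brl(mun, cfg.locale),
            }
        )
    per_cycle = pd.DataFrame(rows)

    # --- totals, counterfactual, impact, sensitivity --------------------
    series = expand_schedule(schedule, params, cfg.convention)
    mh_total, mun_total = totals(series)
    cf = counterfactual_totals(schedule, params, cfg.convention)
    summary = financial_impact((mh_total, mun_total), cf)
    frac = (
        cfg.sensitivity_fraction
        if cfg.sensitivity_fraction is not None
        else params.sensitivity_fraction
    )
    summary = sensitivity(summary, frac)
    log("mh_total", "sum over months of mh_cost", round_cents(mh_total))
    log("municipal_total", "sum over months of municipal_cost",
        round_cents(mun_total))
    log("mh_counterfactual", "n_months * baseline mh_cost", cf[0])
    log("municipal_counterfactual", "n_months * baseline municipal_cost", cf[1])
    log("mh_impact", "counterfactual - actual", round_cents(summary.mh_impact))
    log("municipal_impact", "actual - counterfactual",
        round_cents(summary.municipal_impact))
    for payer, bounds in (("mh", summary.mh_bounds),
                          ("municipal", summary.municipal_bounds)):
        log(f"{payer}_optimistic", "impact * (1 - f)", bounds[0])
        log(f"{payer}_pessimistic", "impact * (1 + f)", bounds[1])

    impact = {
        "horizon_months": schedule.n_months,
        "sensitivity_fraction": str(frac),
        "mh_total": str(round_cents(mh_total)),
        "municipal_total": str(round_cents(mun_total)),
        "mh_counterfactual": str(round_cents(cf[0])),
        "municipal_counterfactual": str(round_cents(cf[1])),
        # published sign convention: the MH impact is a saving (positive),
        # the municipal impact an extra burden (printed negative)
        "mh_impact_signed": str(round_cents(summary.mh_impact)),
        "municipal_impact_signed": str(round_cents(-summary.municipal_impact)),
        "mh_impact_magnitude": str(round_cents(summary.mh_impact)),
        "municipal_impact_magnitude": str(round_cents(summary.municipal_impact)),
        "mh_optimistic": str(summary.mh_bounds[0]),
        "mh_pessimistic": str(summary.mh_bounds[1]),
        "municipal_optimistic": str(summary.municipal_bounds[0]),
        "municipal_pessimistic": str(summary.municipal_bounds[1]),
    }

    # --- stratification --------------------------------------------------
    dependence_df = exit_df = None
    if cfg.roster is not None:
        table = cross_tab(list(cfg.roster))
        dependence_df = table.to_dataframe()
        for (lbl, ind), count in table.cells.items():
            log(f"dependence[{lbl},{ind}]", "municipality tally", count)
        points = exit_projection(
            cfg.roster,
            schedule.horizon_start,
            schedule.horizon_end,
            cfg.eligibility_threshold,
        )
        exit_df = pd.DataFrame(
            {
                "month": [str(p.month) for p in points],
                "n_physicians": [p.n_physicians for p in points],
                "n_municipalities": [p.n_municipalities for p in points],
            }
        )
        log("exit_projection", "monthly roster head-counts", len(points))

    bundle = ReportBundle(
        per_cycle=per_cycle,
        impact=impact,
        dependence=dependence_df,
        exit_series=exit_df,
        audit_log=audit,
    )
    if cfg.out_dir is not None:
        _write_bundle(bundle, cfg)
    return bundle


def _write_bundle(bundle: ReportBundle, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def save_df(df: pd.DataFrame, stem: str, index: bool = False) -> None:
        df.to_csv(out / f"{stem}.csv", index=index)
        (out / f"{stem}.json").write_text(
            df.to_json(orient="table", index=index) + "\n"
        )
        bundle.paths[stem] = out / f"{stem}.csv"

    save_df(bundle.per_cycle.astype(str), "per_cycle_costs")
    (out / "impact_summary.json").write_text(
        json.dumps(bundle.impact, indent=2) + "\n"
    )
    pd.DataFrame([bundle.impact]).to_csv(out / "impact_summary.csv", index=False)
    bundle.paths["impact_summary"] = out / "impact_summary.json"
    if bundle.dependence is not None:
        save_df(bundle.dependence, "dependence_table", index=True)
    if bundle.exit_series is not None:
        save_df(bundle.exit_series, "exit_projection")

    run_log = {
        "seed": cfg.seed,
        "convention": cfg.convention.value,
        "eligibility_threshold": cfg.eligibility_threshold,
        "locale": cfg.locale,
        "parameters": {
            k: str(v) for k, v in cfg.params.model_dump().items()
        },
        "payroll_rules": json.loads(cfg.payroll_rules.model_dump_json()),
        "n_audit_entries": len(bundle.audit_log),
        "audit": bundle.audit_log,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    bundle.paths["run_log"] = out / "run_log.json"


def load_parameters(path: str | Path | None) -> CostParameters:
    """CostParameters from a YAML/JSON mapping (packaged defaults if None)."""
    from .cost_model import default_parameters

    if path is None:
        return default_parameters()
    data = _load_mapping(path)
    try:
        return CostParameters.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"bad cost parameters in {path}: {exc}") from exc


def load_payroll_rules(path: str | Path | None) -> PayrollRules:
    if path is None:
        return default_rules()
    data = _load_mapping(path)
    try:
        return PayrollRules.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"bad payroll rules in {path}: {exc}") from exc


def _load_mapping(path: str | Path) -> dict:
    import yaml

    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{p} must hold a mapping")
    return data
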