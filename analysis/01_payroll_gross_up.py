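"""Gross-up of the program scholarship to a celetist employer cost.

The replacement hire is paid a net wage equal to the monthly scholarship
(R$ 11,865.60).  This script inverts the 2019 tax/contribution schedules to
find the gross, then assembles the employer's monthly and annual cost.
Writes results/payroll_breakdown.json.
"""

import json
from pathlib import Path

from pmmb_impact import default_rules, fmt_brl, gross_from_net, net_from_gross

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rules = default_rules()
    gross = gross_from_net("11865.60", rules)
    b = net_from_gross(gross, rules)

    print(f"scholarship (net target)     {fmt_brl(b.net)}")
    print(f"gross wage                   {fmt_brl(b.gross)}")
    print(f"  employee INSS              {fmt_brl(b.employee_contribution)}")
    print(f"  income tax                 {fmt_brl(b.income_tax)}")
    print(f"monthly employer total       {fmt_brl(b.monthly_employer_total)}")
    print(f"annual employer total        {fmt_brl(b.annual_employer_total)}")
    print()
    print("A municipality replacing one physician therefore spends "
          f"{fmt_brl(b.monthly_employer_total)} per month, "
          f"{fmt_brl(b.annual_employer_total)} per year.")

    OUT.mkdir(exist_ok=True)
    payload = {
        "gross": str(b.gross),
        "employee_contribution": str(b.employee_contribution),
        "income_tax": str(b.income_tax),
        "net": str(b.net),
        "monthly_employer_total": str(b.monthly_employer_total),
        "annual_employer_total": str(b.annual_employer_total),
        "components": {k: str(v) for k, v in b.component_map.items()},
    }
    (OUT / "payroll_breakdown.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(f"\nwrote {OUT / 'payroll_breakdown.json'}")


if __name__ == "__main__":
    main()
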