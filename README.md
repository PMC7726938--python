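# pmmb-impact

Deterministic budget-impact model of withdrawing *Programa Mais Médicos para
o Brasil* (PMMB — More Doctors for Brazil) physicians from the municipalities
of the state of São Paulo between January 2019 and March 2022.

In 2019 the federal allocation rule changed: only municipalities in
vulnerability profiles ≥ 4 keep physician replacement when a three-year PMMB
contract cycle closes. Everywhere else the physician leaves and the
municipality must hire a celetist (CLT) substitute from its own budget. This
package estimates, from the public payer (SUS) perspective and without
discounting, what that rule change costs each payer — the Ministry of Health
(MH) and the municipalities — and how many physicians and municipalities
leave the program. It is written for health-economics and health-workforce
analysts who want the published figures reproducible, auditable and
re-runnable under different parameters.

## Model

For a cycle month with `n` physicians remaining out of a baseline `N`
(departures `Δ = N − n`):

```
MH(n)   = Ref + n·(PS + PCF_pmmb) + Δ·PCF_dif
Mun(n)  = n·(Food + Rent) + Δ·W − Δ·(PCF_pmmb + PCF_dif)        (n < N)
Mun(N)  = N·(Food − PCF_pmmb)                                    (baseline)
```

where `PS` is the monthly scholarship (R$ 11,865.60), `PCF_pmmb` the reduced
variable Primary Care Floor transfer per PMMB-staffed team (R$ 4,000),
`PCF_dif = 7,130 − 4,000 = 3,130` the transfer restored per vacated slot,
`Ref = 6,500 + 7·6,000 = 48,500` the supervision references, `Food = 600`
and `Rent = 2,000` the municipal aid items, and `W` the monthly employer
cost of a substitute hired at a net wage equal to the scholarship. `W` comes
from the payroll module: gross-up of R$ 11,865.60 under the 2019 INSS/IRRF
schedules gives gross R$ 15,809.57, and `W = 15,809.57 × (1 + 0.20 + 0.08)
= 20,236.2496` (INSS employer quota 20%, FGTS 8%).

The cycle schedule is expanded month by month (each closure holds until the
next), summed over the 39-month horizon, and compared with the
counterfactual in which the January 2019 ceiling (N = 2,533) persists;
the per-payer impact is the difference, with fixed ±30% sensitivity bounds.
Separately, municipalities are cross-tabulated by *dependence* (PMMB
physicians as a share of their family-health teams, binned 0–20 … 80–100%)
against the vulnerability indicator, and a monthly exit projection removes
each non-replaced physician at their contract-end month.

## Worked example

```python
from pmmb_impact import (default_parameters, expand_schedule, totals,
                         counterfactual_totals, financial_impact, sensitivity)
from pmmb_impact.synthetic_data import fixture_schedule

params = default_parameters()
schedule = fixture_schedule()          # ten cycle closures, Jan/2019-Mar/2022
mh, mun = totals(expand_schedule(schedule, params))
s = sensitivity(financial_impact((mh, mun),
                                 counterfactual_totals(schedule, params)),
                params.sensitivity_fraction)
print(f"MH total        {mh}")         # 1124135514.00
print(f"municipal total {mun}")        # 593612104.7712
print(f"MH saving       {s.mh_impact}")            # 445071013.20
print(f"municipal burden {s.municipal_impact}")    # 929487904.7712
print(f"municipal bounds {s.municipal_bounds}")
# (Decimal('650641533.34'), Decimal('1208334276.20'))
```

Over 39 months the MH spends R$ 1.124 billion instead of the
R$ 1.569 billion the full program would have cost (a saving of
R$ 445.1 million), while municipalities move from a net receipt to
R$ 593.6 million of spending — an extra burden of R$ 929.5 million
(R$ 650.6 million to R$ 1,208.3 million under ±30% sensitivity).

The numbered drivers under `analysis/` run the same computations as a
narrative: `01_payroll_gross_up.py` (scholarship gross-up and employer
cost), `02_cost_projection.py` (per-cycle table, totals, impacts),
`03_stratification.py` (dependence cross-tab: 373 municipalities of which
86 keep replacement and 131 depend on the program for ≥ 40% of their teams;
exit projection 2,533 → 320 physicians, 373 → 86 municipalities) and
`04_full_report.py` (all tables plus an audited run log). Tables land under
`results/`. The same pipeline is exposed on the command line:

```
pmmb-impact payroll --net 11865.60
pmmb-impact run --out results/report
```

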