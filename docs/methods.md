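# Methods

## Model and assumptions

The package implements a deterministic, payer-perspective budget-impact
model over a fixed 39-month horizon (January 2019 – March 2022, inclusive
whole calendar months). Two payers are tracked: the federal Ministry of
Health (MH) and the São Paulo municipalities participating in the PMMB.
Core assumptions, all fixed-effect:

- **No discounting.** Costs change by cycle, not by time value; monthly
  amounts are summed at face value.
- **No early contract closure.** Every physician serves until their cycle's
  contract-end month (real first-year drop-out is known to be ≥ 20%; an
  exploratory attrition scenario exists but is excluded from all headline
  runs).
- **Immediate replacement.** A municipality losing a physician without
  program replacement hires a celetist substitute in the same month, at a
  net wage equal to the program scholarship.
- **Uniform transfers.** Every family-health team receives the standard
  variable Primary Care Floor (PCF) amounts (R$ 7,130 full, R$ 4,000 with a
  PMMB physician); the slightly higher quilombola/settlement PCF tier does
  not occur in São Paulo and is disregarded.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `scholarship` | 11,865.60 | BRL/physician-month | federal scholarship, also the substitute's net-wage anchor |
| `pcf_full` / `pcf_pmmb` | 7,130.00 / 4,000.00 | BRL/team-month | variable PCF without / with a PMMB physician |
| `pcf_dif` | 3,130.00 | BRL/month | derived `pcf_full − pcf_pmmb`; equality enforced at construction |
| `ref_central`, `ref_decentralized`, `n_decentralized` | 6,500.00, 6,000.00, 7 | BRL/month, count | supervision references (one central, seven state) |
| `rent`, `food` | 2,000.00, 600.00 | BRL/physician-month | municipal aid counterparts |
| `physician_wage_monthly` | 20,236.2496 | BRL/month | substitute's employer cost; see below |
| `sensitivity_fraction` | 0.30 | — | fixed one-way sensitivity half-width |

Payroll defaults are the 2019 schedules: employee INSS flat bands 8/9/11%
with ceiling 5,839.45 (cap 642.34), the monthly IRRF table with top bracket
27.5% and deduction parcel 869.36, employer INSS quota 20%, FGTS 8%,
vacation bonus one third, 13th salary included.

## Numerical choices

- **Exact decimal arithmetic.** All money is `decimal.Decimal`. Products of
  cent-valued parameters with integer head-counts are exact, so per-cycle MH
  cells and all totals carry no floating error. Rounding (half-up, the
  spreadsheet convention) is applied at component *display* boundaries and
  terminal totals only.
- **The replacement wage is kept unrounded.** The employer cost of the
  substitute is 15,809.57 × 1.28 = 20,236.2496 BRL/month. Published tables
  print the cent rounding (20,236.25), but the published municipal cost
  cells and the 39-month municipal total are only reproduced — down to
  their sub-cent drift (e.g. …099.85 at the first closure) — with the
  unrounded product. The default therefore stores full precision, and a
  cross-check asserts the parameter equals the live payroll derivation.
- **Annual employer cost.** The annual composition is 12 monthly totals +
  vacation pay with one-third bonus + employer quota on it + 13th salary +
  FGTS on the 13th, accumulated at full precision and rounded once at the
  end (285,204.64). The termination-notice items and the employer quota on
  the 13th are excluded: the printed annual total is only reproducible
  without them, despite the label claiming termination is included. The
  composition is configurable per component label.
- **Gross-from-net inversion.** Per-regime linear inversion (each
  contribution band or the cap, crossed with each tax bracket) with
  verification, plus a cent-grid bisection fallback; non-convergence raises
  rather than returning silently. Ties go to the smaller gross.
- **Non-injectivity at band edges.** Because the employee INSS schedule is
  flat-band (the band rate applies to the whole gross), the net wage drops
  discontinuously at the two internal band edges, so gross↔net is not
  injective on narrow windows (~20–65 BRL) below the contribution ceiling.
  The inversion contract — the returned gross reproduces the target net
  within R$ 0.01 — holds everywhere; the strict round-trip identity holds
  on the injective region, which includes the entire wage range this model
  uses (all targets are far above the ceiling).
- **Month weighting.** Each cycle is in force from its effective month to
  the month before the next cycle's effective month; the last runs to the
  horizon end. For the packaged schedule this yields weights
  [2, 1, 2, 2, 6, 4, 7, 11, 3, 1] summing to 39. The source table prints
  its seventh row with a duplicated "11th cycle" label; it is treated as
  the 14th cycle effective June 2020, the only reading under which the
  published 39-month totals close. No pro-rating of partial months.
- **Baseline municipal convention.** The literal baseline formula stated
  with the model (aid plus transfer as costs) contradicts the published
  baseline row, which equals N × (food − PCF_pmmb): food aid booked as
  outlay, the reduced PCF transfer as receipt, rent as non-cash. The
  default convention (`as_printed_table`) follows the published row; the
  literal form is retained as `as_printed_box` for comparison.
- **Impact signs.** Impacts are stored as magnitudes with fixed payer
  directions (MH: saving; municipalities: burden); the report layer renders
  the published convention (municipal impact negative). Sensitivity bounds
  are magnitudes (optimistic, pessimistic).
- **Dependence bins** are half-open with a closed top bin
  ([0,20), …, [80,100]); the published row labels overlap at the edges, so
  the standard convention is adopted. The replacement-eligibility rule is
  `indicator ≥ 4` over whatever indicator range the data carries (the
  running text variously says "4 to 6" and "4 to 8"; the packaged data has
  six profiles).
- **Exit timing.** A physician is counted through the month *before* their
  contract-end month; the vacancy takes effect in the end month, matching
  the cycle schedule's effective months. A municipality participates while
  it holds ≥ 1 program physician — the reading that reproduces both
  published endpoint pairs (2,533 → 320 physicians and 373 → 86
  municipalities) simultaneously.

## Synthetic roster generation

Per-municipality physician counts were never published; only the marginals
were (373 municipalities, 2,533 physicians, the dependence × vulnerability
cross-tab, and the statewide head-count at each cycle closure). The
generator emulates the public-registry extraction by constructing *one*
roster consistent with all of them:

1. Municipalities are laid out cell by cell from the exact cross-tab (or
   from two marginals combined by the northwest-corner rule).
2. Each starts at the minimum head-count its dependence bin admits (1,
   except 2 in the 60–80% bin, where no integer team count places a single
   physician); remaining physicians are dealt by the seeded generator —
   within the eligibility groups when a contract-end profile pins the
   ineligible total (here 2,213 = the sum of cycle drops, leaving 320 with
   the 86 eligible municipalities).
3. Team counts are the smallest integer keeping the municipality inside its
   bin, so `physicians ≤ teams` holds by construction.
4. Contract-end months for ineligible-municipality physicians are assigned
   from the cycle-drop profile in seeded order; eligible physicians (whose
   departures are replaced) end at the horizon end.

Exact quota allocation first, randomized residual second: reproducibility
over realism. Generation is deterministic given the seed, and the reported
quantities are seed-invariant because the constraints bind them. What the
roster does *not* emulate: real geography, team-size distributions,
correlation between municipality size and vulnerability, or within-
municipality contract heterogeneity. Tests passing on it show the
arithmetic and the classification rules are right, not that any particular
real municipality's burden is.

The exploratory attrition scenario thins the baseline cohort binomially at
rate *r* after the first year (`apply_attrition`); it is a sensitivity
device only and feeds no headline figure.

## Known limitations

- Fixed-effect assumptions (no drop-out, immediate replacement, uniform
  salaries) push the municipal burden toward an upper envelope; the ±30%
  band is the model's only acknowledgment of regional heterogeneity.
- PCF accounting is per physician, not per team; multi-physician teams are
  not modelled.
- The payroll module covers the packaged 2019 schedule vintages and the
  standard CLT charges only — no unions, benefits or historical tables.
- The published reduction of "76.9% of vacancies" matches the municipality
  share (287/373), not the physician share (2,213/2,533 = 87.4%); the
  stratification driver reports both, explicitly labelled.
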