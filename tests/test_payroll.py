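"""Payroll gross/net arithmetic under the 2019 schedules and toy rule sets."""

from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from pmmb_impact import (
    employee_contribution,
    gross_from_net,
    income_tax,
    net_from_gross,
)
from pmmb_impact.errors import DomainError
from pmmb_impact.payroll import ContributionBand, PayrollRules, TaxBracket

D = Decimal


def toy_rules(**overrides):
    """Zero-tax, zero-contribution rules unless overridden."""
    base = dict(
        contribution_bands=[ContributionBand(upper=None, rate="0")],
        employee_contribution_cap=None,
        tax_brackets=[TaxBracket(upper=None, rate="0")],
        employer_quota_rate="0",
        severance_fund_rate="0",
    )
    base.update(overrides)
    return PayrollRules(**base)


class TestEmployeeContribution:
    def test_capped_above_ceiling(self, rules):
        assert employee_contribution(D("15809.57"), rules) == D("642.34")

    def test_zero_gross(self, rules):
        assert employee_contribution(D("0"), rules) == D("0.00")

    def test_toy_one_band_uncapped(self):
        r = toy_rules(
            contribution_bands=[ContributionBand(upper=None, rate="0.08")]
        )
        assert employee_contribution(D("1000.00"), r) == D("80.00")

    def test_band_rate_applies_to_whole_gross(self, rules):
        # flat-band schedule: 9% of the full wage inside the second band
        assert employee_contribution(D("2000.00"), rules) == D("180.00")

    def test_negative_gross_rejected(self, rules):
        with pytest.raises(DomainError):
            employee_contribution(D("-1"), rules)


class TestIncomeTax:
    def test_top_bracket_published_value(self, rules):
        assert income_tax(D("15167.23"), rules) == D("3301.63")

    def test_exempt_below_threshold(self, rules):
        assert income_tax(D("0"), rules) == D("0.00")
        assert income_tax(D("1903.98"), rules) == D("0.00")

    def test_interior_bracket_matches_piecewise_oracle(self):
        # toy 3-bracket table with parcels built for continuity
        r = toy_rules(
            tax_brackets=[
                TaxBracket(upper="1000", rate="0"),
                TaxBracket(upper="2000", rate="0.10", deduction="100"),
                TaxBracket(upper=None, rate="0.20", deduction="300"),
            ]
        )

        def piecewise(x: Decimal) -> Decimal:
            # integrate marginal rates band by band
            bands = [(D("0"), D("1000"), D("0")),
                     (D("1000"), D("2000"), D("0.10")),
                     (D("2000"), D("Infinity"), D("0.20"))]
            tax = D(0)
            for lo, hi, rate in bands:
                if x > lo:
                    tax += (min(x, hi) - lo) * rate
            return tax.quantize(D("0.01"))

        for taxable in ("500", "1500", "1999.99", "2000", "2500", "10000"):
            assert income_tax(D(taxable), r) == piecewise(D(taxable))

    def test_continuous_at_bracket_boundaries(self, rules):
        # at each internal boundary the two adjacent formulas agree
        brackets = rules.tax_brackets
        for below, above in zip(brackets, brackets[1:]):
            u = below.upper
            from_below = max(u * below.rate - below.deduction, D(0))
            from_above = max(u * above.rate - above.deduction, D(0))
            assert abs(from_below - from_above) <= D("0.01")

    def test_negative_taxable_rejected(self, rules):
        with pytest.raises(DomainError):
            income_tax(D("-0.01"), rules)


class TestNetFromGross:
    def test_published_breakdown(self, rules):
        b = net_from_gross(D("15809.57"), rules)
        assert b.employee_contribution == D("642.34")
        assert b.income_tax == D("3301.63")
        assert b.net == D("11865.60")
        assert b.monthly_employer_total.quantize(D("0.01")) == D("20236.25")
        assert b.component_map["vacation_bonus"] == D("21079.43")
        assert b.component_map["thirteenth_salary"] == D("15809.57")
        assert b.component_map["employer_quota"] == D("3161.91")
        assert b.component_map["severance_fund"] == D("1264.77")

    def test_published_annual_total(self, rules):
        b = net_from_gross(D("15809.57"), rules)
        assert abs(b.annual_employer_total - D("285204.64")) <= D("0.05")

    def test_toy_identity(self):
        b = net_from_gross(D("100.00"), toy_rules())
        assert b.net == D("100.00")
        assert b.monthly_employer_total == D("100.00")

    def test_net_decomposition_to_the_cent(self, rules):
        for gross in ("1000", "3000", "5839.45", "15809.57", "42000"):
            b = net_from_gross(D(gross), rules)
            assert b.net == b.gross - b.employee_contribution - b.income_tax

    def test_employer_total_ratio_exact(self, rules):
        b = net_from_gross(D("12345.67"), rules)
        assert b.monthly_employer_total / b.gross == D("1.28")

    def test_monotone_in_gross_above_contribution_ceiling(self, rules):
        grid = [D("5900") + 250 * i for i in range(200)]
        nets = [net_from_gross(g, rules).net for g in grid]
        assert all(b >= a for a, b in zip(nets, nets[1:]))

    def test_monotone_within_each_contribution_band(self, rules):
        for lo, hi in [(D("100"), D("1751.81")), (D("1751.82"), D("2919.72")),
                       (D("2919.73"), D("5839.45"))]:
            step = (hi - lo) / 50
            grid = [lo + i * step for i in range(51)]
            nets = [net_from_gross(g.quantize(D("0.01")), rules).net
                    for g in grid]
            assert all(b >= a for a, b in zip(nets, nets[1:]))


class TestGrossFromNet:
    def test_published_gross_up(self, rules):
        assert gross_from_net(D("11865.60"), rules) == D("15809.57")

    def test_toy_identity(self):
        r = toy_rules()
        for x in ("0.00", "1.00", "1234.56", "99999.99"):
            assert gross_from_net(D(x), r) == D(x)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(cents=st.integers(min_value=600_000, max_value=5_000_000))
    def test_round_trip_identity_above_ceiling(self, rules, cents):
        # injective region: the employee contribution is the flat cap
        gross = D(cents) / 100
        net = net_from_gross(gross, rules).net
        assert abs(gross_from_net(net, rules) - gross) <= D("0.01")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(cents=st.integers(min_value=100_000, max_value=5_000_000))
    def test_round_trip_reproduces_net_everywhere(self, rules, cents):
        # near the band edges several grosses share a net; the recovered
        # gross must still reproduce the target net to the cent
        gross = D(cents) / 100
        net = net_from_gross(gross, rules).net
        recovered = gross_from_net(net, rules)
        assert abs(net_from_gross(recovered, rules).net - net) <= D("0.01")

    def test_negative_target_rejected(self, rules):
        with pytest.raises(DomainError):
            gross_from_net(D("-5"), rules)
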