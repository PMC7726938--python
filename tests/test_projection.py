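"""Schedule expansion, payer totals, counterfactual, impact, sensitivity."""

from decimal import Decimal

import pytest

from pmmb_impact import (
    CycleEntry,
    CycleSchedule,
    Month,
    counterfactual_totals,
    expand_schedule,
    financial_impact,
    read_schedule,
    sensitivity,
    totals,
    write_schedule,
)
from pmmb_impact.cost_model import CostParameters, CycleState, mh_monthly_cost
from pmmb_impact.errors import DomainError, ValidationError

D = Decimal


def make_schedule(entries, start, end):
    return CycleSchedule(
        entries=tuple(
            CycleEntry(label=f"c{i}", effective_month=Month.parse(m),
                       n_physicians=n)
            for i, (m, n) in enumerate(entries)
        ),
        horizon_start=Month.parse(start),
        horizon_end=Month.parse(end),
    )


class TestScheduleStructure:
    def test_fixture_month_weights(self, schedule):
        assert schedule.month_weights() == [2, 1, 2, 2, 6, 4, 7, 11, 3, 1]
        assert sum(schedule.month_weights()) == schedule.n_months == 39

    def test_single_entry_constant_series(self, params):
        s = make_schedule([("2019-01", 10)], "2019-01", "2019-03")
        series = expand_schedule(s, params)
        assert len(series.records) == 3
        assert len({(r.n_physicians, r.mh_cost, r.municipal_cost)
                    for r in series.records}) == 1

    def test_fixture_horizon_has_39_records(self, schedule, params):
        assert len(expand_schedule(schedule, params).records) == 39

    @pytest.mark.parametrize(
        "entries, start, end",
        [
            ([("2019-02", 5)], "2019-01", "2019-06"),   # first not at start
            ([("2019-01", 5), ("2019-01", 4)], "2019-01", "2019-06"),
            ([("2019-01", 5), ("2019-03", 6)], "2019-01", "2019-06"),  # grows
            ([("2019-01", 5), ("2019-09", 4)], "2019-01", "2019-06"),  # outside
        ],
    )
    def test_invalid_schedules_rejected(self, entries, start, end):
        with pytest.raises(ValidationError):
            make_schedule(entries, start, end)

    def test_month_outside_horizon_rejected(self, schedule):
        with pytest.raises(ValidationError):
            schedule.count_at(Month.parse("2022-04"))

    def test_round_trips_through_delimited_text(self, schedule, tmp_path):
        path = tmp_path / "schedule.csv"
        write_schedule(schedule, path)
        back = read_schedule(path, schedule.horizon_end)
        assert back == schedule


class TestTotals:
    def test_fixture_mh_total_exact(self, schedule, params):
        mh, _ = totals(expand_schedule(schedule, params))
        assert mh == D("1124135514.00")

    def test_fixture_municipal_total(self, schedule, params):
        _, mun = totals(expand_schedule(schedule, params))
        assert abs(mun - D("593612104.77")) <= D("0.05")

    def test_zero_cost_series(self):
        p = CostParameters(
            scholarship="0", pcf_full="0", pcf_pmmb="0", ref_central="0",
            ref_decentralized="0", n_decentralized=0, rent="0", food="0",
            physician_wage_monthly="0",
        )
        s = make_schedule([("2019-01", 3)], "2019-01", "2019-05")
        assert totals(expand_schedule(s, p)) == (D(0), D(0))

    def test_totals_equal_weight_dot_product(self, schedule, params):
        # month-by-month accumulation agrees with per-cycle weighting
        series = expand_schedule(schedule, params)
        mh, mun = totals(series)
        weights = schedule.month_weights()
        by_cycle_mh = by_cycle_mun = D(0)
        for w, entry in zip(weights, schedule.entries):
            month = entry.effective_month
            rec = next(r for r in series.records if r.month == month)
            by_cycle_mh += w * rec.mh_cost
            by_cycle_mun += w * rec.municipal_cost
        assert (mh, mun) == (by_cycle_mh, by_cycle_mun)

    def test_empty_series_rejected(self):
        from pmmb_impact.projection import MonthlyCostSeries

        with pytest.raises(ValidationError):
            totals(MonthlyCostSeries(records=()))


class TestCounterfactual:
    def test_fixture_mh_counterfactual(self, schedule, params):
        mh_cf, mun_cf = counterfactual_totals(schedule, params)
        assert mh_cf == 39 * D("40236064.80") == D("1569206527.20")
        assert mun_cf == 39 * D("-8612200.00") == D("-335875800.00")

    def test_zero_physician_baseline_only_references_remain(self, params):
        s = make_schedule([("2019-01", 0)], "2019-01", "2022-03")
        mh_cf, mun_cf = counterfactual_totals(s, params)
        assert mh_cf == 39 * D("48500.00")
        assert mun_cf == D(0)


class TestImpactAndSensitivity:
    def test_fixture_impacts(self, schedule, params):
        actual = totals(expand_schedule(schedule, params))
        cf = counterfactual_totals(schedule, params)
        s = financial_impact(actual, cf)
        assert s.mh_impact == D("445071013.20")
        assert abs(s.municipal_impact - D("929487904.77")) <= D("0.05")

    def test_impact_conserves_counterfactual_decomposition(self, schedule,
                                                           params):
        actual = totals(expand_schedule(schedule, params))
        cf = counterfactual_totals(schedule, params)
        s = financial_impact(actual, cf)
        assert s.mh_impact + s.mh_total == s.mh_counterfactual

    def test_constant_schedule_has_zero_impact(self, params):
        s = make_schedule([("2019-01", 100)], "2019-01", "2020-12")
        impact = financial_impact(
            totals(expand_schedule(s, params)),
            counterfactual_totals(s, params),
        )
        assert impact.mh_impact == impact.municipal_impact == D(0)

    def test_fixture_sensitivity_bounds(self, schedule, params):
        s = financial_impact(
            totals(expand_schedule(schedule, params)),
            counterfactual_totals(schedule, params),
        )
        s = sensitivity(s, params.sensitivity_fraction)
        assert s.municipal_bounds == (D("650641533.34"), D("1208334276.20"))
        assert s.mh_bounds == (D("311549709.24"), D("578592317.16"))

    @pytest.mark.parametrize(
        "impact, f, expected",
        [("0", "0.30", ("0.00", "0.00")), ("100", "0.30", ("70.00", "130.00"))],
    )
    def test_forced_arithmetic(self, impact, f, expected):
        from pmmb_impact.projection import ImpactSummary

        base = ImpactSummary(
            mh_total=D(0), municipal_total=D(0), mh_counterfactual=D(0),
            municipal_counterfactual=D(0), mh_impact=D(impact),
            municipal_impact=D(impact),
        )
        out = sensitivity(base, D(f))
        assert out.mh_bounds == (D(expected[0]), D(expected[1]))

    def test_fraction_outside_unit_interval_rejected(self):
        from pmmb_impact.projection import ImpactSummary

        base = ImpactSummary(
            mh_total=D(0), municipal_total=D(0), mh_counterfactual=D(0),
            municipal_counterfactual=D(0), mh_impact=D(1),
            municipal_impact=D(1),
        )
        with pytest.raises(DomainError):
            sensitivity(base, D("1.5"))


class TestMonotonicityInDepartures:
    def test_removing_more_physicians_moves_both_payers_monotonically(
        self, params
    ):
        mh_totals, mun_totals = [], []
        for k in range(0, 60, 10):
            s = make_schedule(
                [("2019-01", 100), ("2019-04", 100 - k)], "2019-01", "2019-12"
            )
            mh, mun = totals(expand_schedule(s, params))
            mh_totals.append(mh)
            mun_totals.append(mun)
        assert all(b < a for a, b in zip(mh_totals, mh_totals[1:]))
        assert all(b > a for a, b in zip(mun_totals, mun_totals[1:]))
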