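"""Exposure engine: censoring rules, unit arithmetic, weighted summaries,
and equivalence with an independent nested-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ngra.exposure import (
    compute_exposures,
    daily_intake,
    mean_concentrations,
    oim,
    resolve_concentration,
    summarize,
    translate_consumption,
    weighted_quantile,
)
from ngra.model import (
    ConcentrationSample,
    ConsumptionRecord,
    ResultType,
    Scenario,
    TranslationEntry,
)
from ngra.synth import SyntheticScenario, generate_scenario


def sample(rt, **kw):
    return ConcentrationSample(substance_code="S-PPP", commodity_code="wheat",
                               result_type=rt, **kw)


class TestResolveConcentration:
    @pytest.mark.parametrize(
        "s, scenario, expected",
        [
            (sample(ResultType.ND_LOD, lod=0.01), Scenario.upper_bound, 0.01),
            (sample(ResultType.ND_LOQ, loq=0.03), Scenario.lower_bound, 0.0),
            (sample(ResultType.ND_LOQ, loq=0.03), Scenario.upper_bound, 0.03),
            (sample(ResultType.ND_LOD, lod=0.01), Scenario.lower_bound, 0.0),
            (sample(ResultType.VAL, value=0.2), Scenario.lower_bound, 0.2),
            (sample(ResultType.VAL, value=0.2), Scenario.upper_bound, 0.2),
        ],
    )
    def test_substitution_rules(self, s, scenario, expected):
        assert resolve_concentration(s, scenario) == expected


class TestTranslateConsumption:
    def make_records(self, foods_amounts):
        return [
            ConsumptionRecord(subject_id="s1", day=1, food_code=f, amount=a,
                              body_weight=70, survey_weight=1)
            for f, a in foods_amounts
        ]

    def test_percent_scaling(self):
        out = translate_consumption(
            self.make_records([("bread", 100.0)]),
            [TranslationEntry(food_code="bread", commodity_code="wheat",
                              percent=70)],
        )
        assert out.table["amount"].tolist() == [70.0]
        assert out.untranslated == ()

    def test_multi_commodity_expansion(self):
        out = translate_consumption(
            self.make_records([("bread", 100.0)]),
            [
                TranslationEntry(food_code="bread", commodity_code="wheat",
                                 percent=70),
                TranslationEntry(food_code="bread", commodity_code="water",
                                 percent=30),
            ],
        )
        got = dict(zip(out.table["commodity_code"], out.table["amount"]))
        assert got == {"wheat": 70.0, "water": 30.0}

    def test_untranslated_food_diagnosed_not_dropped_silently(self):
        out = translate_consumption(
            self.make_records([("mystery", 50.0)]),
            [TranslationEntry(food_code="bread", commodity_code="wheat",
                              percent=70)],
        )
        assert out.table.empty
        assert out.untranslated == ("mystery",)


class TestDailyIntakeAndOim:
    def test_unit_arithmetic(self):
        # 70 g at 0.1 mg/kg over 70 kg -> 0.1 ug/kg bw/day
        assert daily_intake({"wheat": 70.0}, {"wheat": 0.1}, 70.0) == \
            pytest.approx(0.1)

    def test_two_commodities(self):
        got = daily_intake({"a": 50.0, "b": 100.0}, {"a": 0.2, "b": 0.1}, 50.0)
        assert got == pytest.approx(0.4)

    def test_zero_consumption_day(self):
        assert daily_intake({}, {"wheat": 0.5}, 70.0) == 0.0

    def test_oim_is_day_mean(self):
        assert oim([1.0, 2.0]) == 1.5
        assert oim([0.8]) == 0.8
        assert oim([0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            oim([])


class TestWeightedSummary:
    def test_equal_weights_match_unweighted(self):
        vals = {f"s{i}": float(v) for i, v in enumerate([1, 2, 3])}
        w = {k: 1.0 for k in vals}
        est = summarize("S-PPP", Scenario.upper_bound, vals, w)
        assert est.weighted_mean == 2.0
        assert est.weighted_median == 2.0

    def test_weighted_mean_arithmetic(self):
        est = summarize("S-PPP", Scenario.upper_bound,
                        {"a": 0.0, "b": 10.0}, {"a": 9.0, "b": 1.0})
        assert est.weighted_mean == pytest.approx(1.0)

    def test_p95_equal_weights_linear_interpolation(self):
        # frozen from the unweighted linear-interpolation quantile on 1..100
        vals = np.arange(1.0, 101.0)
        got = weighted_quantile(vals, np.ones(100), 0.95)
        assert got == pytest.approx(95.05, abs=1e-12)
        assert got == pytest.approx(np.percentile(vals, 95))

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=40),
           st.floats(0, 1))
    def test_equal_weights_reduce_to_numpy(self, values, q):
        got = weighted_quantile(values, np.ones(len(values)), q)
        assert got == pytest.approx(np.percentile(values, 100 * q), rel=1e-9,
                                    abs=1e-9)

    def test_reference_implementation_agreement(self):
        # independent loop-based reference for the weighted definition
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(2, 30)
            v = rng.normal(size=n)
            w = rng.uniform(0.1, 3.0, size=n)
            q = float(rng.uniform())
            order = np.argsort(v)
            sv, sw = v[order], w[order]
            total = sw.sum()
            positions = []
            cum = 0.0
            for wi in sw:
                cum += wi
                positions.append((cum - wi) / (total - wi))
            # manual linear interpolation
            if q <= positions[0]:
                expected = sv[0]
            elif q >= positions[-1]:
                expected = sv[-1]
            else:
                j = int(np.searchsorted(positions, q, side="right")) - 1
                p0, p1 = positions[j], positions[j + 1]
                expected = sv[j] + (sv[j + 1] - sv[j]) * (q - p0) / (p1 - p0)
            assert weighted_quantile(v, w, q) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_summary_within_min_max(self, small_scenario):
        codes = [a.code for a in small_scenario.annotations]
        ests = compute_exposures(
            small_scenario.concentrations, small_scenario.consumption,
            small_scenario.translation, Scenario.upper_bound, substances=codes,
        )
        for est in ests.values():
            lo = min(est.per_subject_oim.values())
            hi = max(est.per_subject_oim.values())
            for stat in (est.weighted_mean, est.weighted_median,
                         est.weighted_p95):
                assert lo - 1e-12 <= stat <= hi + 1e-12


def oracle_exposures(concentrations, consumption, translation, scenario):
    """Independent nested-loop implementation of the whole engine."""
    resolved = {}
    for s in concentrations:
        if s.result_type is ResultType.VAL:
            c = s.value
        elif scenario is Scenario.lower_bound:
            c = 0.0
        else:
            c = s.lod if s.result_type is ResultType.ND_LOD else s.loq
        resolved.setdefault((s.substance_code, s.commodity_code), []).append(c)
    pooled = {k: sum(v) / len(v) for k, v in resolved.items()}
    trans = {}
    for t in translation:
        trans.setdefault(t.food_code, []).append((t.commodity_code, t.percent))
    subjects = {}
    for r in consumption:
        subjects.setdefault(r.subject_id, {"bw": r.body_weight,
                                           "sw": r.survey_weight, "days": {}})
        subjects[r.subject_id]["days"].setdefault(r.day, []).append(
            (r.food_code, r.amount)
        )
    substances = sorted({k[0] for k in pooled})
    out = {}
    for code in substances:
        per_subject = {}
        for sid, info in subjects.items():
            day_intakes = []
            for day in sorted(info["days"]):
                ug = 0.0
                for food, amount in info["days"][day]:
                    for commodity, percent in trans.get(food, []):
                        conc = pooled.get((code, commodity))
                        if conc is not None:
                            ug += amount * percent / 100.0 * conc
                day_intakes.append(ug / info["bw"])
            per_subject[sid] = sum(day_intakes) / len(day_intakes)
        weights = {sid: info["sw"] for sid, info in subjects.items()}
        mean = sum(weights[s] * per_subject[s] for s in per_subject) / \
            sum(weights.values())
        out[code] = (per_subject, mean)
    return out


class TestEngineAgainstOracle:
    def test_tiny_scenario_matches_nested_loops(self):
        """<= 5 subjects x 2 days x 3 foods; agreement to 1e-12 relative."""
        rng = np.random.default_rng(42)
        foods = ["F1", "F2", "F3"]
        commodities = ["C1", "C2"]
        translation = [
            TranslationEntry(food_code="F1", commodity_code="C1", percent=70),
            TranslationEntry(food_code="F1", commodity_code="C2", percent=30),
            TranslationEntry(food_code="F2", commodity_code="C2", percent=110),
            TranslationEntry(food_code="F3", commodity_code="C1", percent=50),
        ]
        consumption = []
        for i in range(5):
            bw = float(rng.uniform(50, 90))
            sw = float(rng.uniform(0.5, 2.0))
            for day in (1, 2):
                for f in foods:
                    consumption.append(
                        ConsumptionRecord(
                            subject_id=f"s{i}", day=day, food_code=f,
                            amount=float(rng.uniform(0, 200)),
                            body_weight=bw, survey_weight=sw,
                        )
                    )
        concentrations = []
        for code in ("A-PPP", "B-TOX"):
            for c in commodities:
                for _ in range(4):
                    u = rng.random()
                    if u < 0.3:
                        concentrations.append(ConcentrationSample(
                            substance_code=code, commodity_code=c,
                            result_type=ResultType.ND_LOD, lod=0.01, loq=0.05))
                    elif u < 0.5:
                        concentrations.append(ConcentrationSample(
                            substance_code=code, commodity_code=c,
                            result_type=ResultType.ND_LOQ, lod=0.01, loq=0.05))
                    else:
                        concentrations.append(ConcentrationSample(
                            substance_code=code, commodity_code=c,
                            result_type=ResultType.VAL,
                            value=float(rng.uniform(0.01, 1.0))))
        for scenario in Scenario:
            engine = compute_exposures(concentrations, consumption,
                                       translation, scenario)
            oracle = oracle_exposures(concentrations, consumption,
                                      translation, scenario)
            assert set(engine) == set(oracle)
            for code, est in engine.items():
                per_subject, mean = oracle[code]
                assert est.per_subject_oim == pytest.approx(per_subject,
                                                            rel=1e-12)
                assert est.weighted_mean == pytest.approx(mean, rel=1e-12)

    def test_scenario_ordering_over_seeds(self):
        """lower bound <= upper bound, element-wise, across seeds."""
        for seed in range(1, 6):
            b = generate_scenario(SyntheticScenario(n_subjects=40, seed=seed))
            codes = [a.code for a in b.annotations]
            lo = compute_exposures(b.concentrations, b.consumption,
                                   b.translation, Scenario.lower_bound,
                                   substances=codes)
            hi = compute_exposures(b.concentrations, b.consumption,
                                   b.translation, Scenario.upper_bound,
                                   substances=codes)
            for code in codes:
                for stat in ("weighted_mean", "weighted_median",
                             "weighted_p95"):
                    assert getattr(lo[code], stat) <= \
                        getattr(hi[code], stat) + 1e-15

    def test_full_censoring_limit(self):
        """nondetect_fraction = 1: lower bound identically 0, upper bound
        equals intake at the limits."""
        b = generate_scenario(
            SyntheticScenario(n_subjects=30, nondetect_fraction=1.0, seed=2)
        )
        assert all(s.result_type is not ResultType.VAL
                   for s in b.concentrations)
        codes = [a.code for a in b.annotations]
        lo = compute_exposures(b.concentrations, b.consumption, b.translation,
                               Scenario.lower_bound, substances=codes)
        for est in lo.values():
            assert est.weighted_mean == 0.0 and est.weighted_p95 == 0.0
        hi = compute_exposures(b.concentrations, b.consumption, b.translation,
                               Scenario.upper_bound, substances=codes)
        pooled = mean_concentrations(b.concentrations, Scenario.upper_bound)
        # substituted limits are positive, so upper-bound exposure is too
        assert all(v > 0 for v in pooled.values())
        assert any(est.weighted_mean > 0 for est in hi.values())

    def test_body_weight_scaling_inverse(self):
        records = [
            ConsumptionRecord(subject_id="s1", day=d, food_code="F1",
                              amount=100.0, body_weight=60.0, survey_weight=1)
            for d in (1, 2)
        ]
        scaled = [
            ConsumptionRecord(subject_id="s1", day=r.day, food_code="F1",
                              amount=100.0, body_weight=r.body_weight * 2,
                              survey_weight=1)
            for r in records
        ]
        translation = [TranslationEntry(food_code="F1", commodity_code="C1",
                                        percent=80)]
        conc = [ConcentrationSample(substance_code="A-PPP",
                                    commodity_code="C1",
                                    result_type=ResultType.VAL, value=0.5)]
        base = compute_exposures(conc, records, translation,
                                 Scenario.upper_bound)["A-PPP"]
        half = compute_exposures(conc, scaled, translation,
                                 Scenario.upper_bound)["A-PPP"]
        assert half.weighted_mean == pytest.approx(base.weighted_mean / 2)

    def test_upper_bound_mean_converges_to_analytic(self):
        """For a fully-quantified substance the weighted mean approaches the
        analytic expectation as n_subjects grows (Monte-Carlo error)."""
        # one food -> one commodity at 100%, constant concentration:
        # exposure_i = (mean daily amount)_i * conc / bw_i exactly, so the
        # engine must reproduce the analytic weighted mean on the realized
        # amounts to floating-point accuracy; convergence in n is then the
        # law of large numbers on the amounts themselves.
        rng = np.random.default_rng(9)
        errors = []
        for n in (50, 800):
            records = []
            for i in range(n):
                bw = 70.0
                for day in (1, 2):
                    records.append(ConsumptionRecord(
                        subject_id=f"s{i:05d}", day=day, food_code="F1",
                        amount=float(rng.gamma(2.0, 60.0)), body_weight=bw,
                        survey_weight=1.0))
            translation = [TranslationEntry(food_code="F1",
                                            commodity_code="C1", percent=100)]
            conc = [ConcentrationSample(substance_code="A-PPP",
                                        commodity_code="C1",
                                        result_type=ResultType.VAL,
                                        value=0.35)]
            est = compute_exposures(conc, records, translation,
                                    Scenario.upper_bound)["A-PPP"]
            analytic = 2.0 * 60.0 * 0.35 / 70.0  # E[gamma(2,60)] * conc / bw
            errors.append(abs(est.weighted_mean - analytic))
        assert errors[1] < errors[0]  # shrinking Monte-Carlo error
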