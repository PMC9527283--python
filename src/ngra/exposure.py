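"""Chronic dietary exposure under the observed-individual-mean (OIM) model.

The engine turns a concentration table (mg substance / kg raw commodity),
a consumption diary (g food / day per subject) and a food-to-commodity
translation table into per-substance chronic exposure distributions in
ug substance / kg body weight / day:

1. censored concentrations are resolved per scenario — non-detects count
   as 0 in the *lower bound* and as their LOD/LOQ in the *upper bound*;
2. per substance x commodity, samples are pooled to their scenario-resolved
   arithmetic mean (the chronic-exposure convention used here);
3. consumed foods are expanded to raw commodities via the translation
   percentages;
4. each subject-day intake is sum(amount_g x conc_mg_per_kg) / body_weight_kg,
   which is ug/kg bw/day since 1 g x 1 mg/kg = 1 ug;
5. the OIM is the subject's arithmetic mean over their recall days, and
   population summaries (mean, median, p95) are weighted by the survey
   weights.

Subjects who never consume a contributing food are retained with OIM = 0:
the chronic population distribution includes non-consumers. Foods missing
from the translation table contribute nothing and are reported in an
``untranslated`` diagnostic list rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ngra.model import (
    ConcentrationSample,
    ConsumptionRecord,
    ExposureEstimate,
    ResultType,
    Scenario,
    TranslationEntry,
)


def resolve_concentration(sample: ConcentrationSample, scenario: Scenario) -> float:
    """Resolve one possibly-censored measurement to a point value in mg/kg.

    Quantified results keep their value in both scenarios. Non-detects are
    0 in the lower bound; in the upper bound they take the limit they were
    censored at (LOD for ND_LOD, LOQ for ND_LOQ).
    """
    scenario = Scenario(scenario)
    if sample.result_type is ResultType.VAL:
        return float(sample.value)
    if scenario is Scenario.lower_bound:
        return 0.0
    if sample.result_type is ResultType.ND_LOD:
        return float(sample.lod)
    return float(sample.loq)


def mean_concentrations(
    samples: Iterable[ConcentrationSample], scenario: Scenario
) -> dict[tuple[str, str], float]:
    """Scenario-resolved arithmetic mean per (substance, commodity), mg/kg."""
    sums: dict[tuple[str, str], list[float]] = {}
    for s in samples:
        sums.setdefault((s.substance_code, s.commodity_code), []).append(
            resolve_concentration(s, scenario)
        )
    return {key: float(np.mean(vals)) for key, vals in sums.items()}


@dataclass(frozen=True)
class TranslatedConsumption:
    """Commodity-level consumption plus the untranslated-food diagnostic."""

    table: pd.DataFrame  # columns: subject_id, day, commodity_code, amount,
    #          body_weight, survey_weight  (amount in g/day of raw commodity)
    untranslated: tuple[str, ...]  # food codes with no translation entry


def translate_consumption(
    records: Sequence[ConsumptionRecord],
    translation: Sequence[TranslationEntry],
) -> TranslatedConsumption:
    """Expand consumed foods into raw-commodity amounts.

    Each diary row (subject, day, food, amount) becomes one row per
    translation entry for that food, with amount scaled by percent/100.
    Foods absent from the translation table yield no commodity rows and
    are collected in the diagnostic list.
    """
    cons = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "day": [r.day for r in records],
            "food_code": [r.food_code for r in records],
            "amount": [r.amount for r in records],
            "body_weight": [r.body_weight for r in records],
            "survey_weight": [r.survey_weight for r in records],
        }
    )
    trans = pd.DataFrame(
        {
            "food_code": [t.food_code for t in translation],
            "commodity_code": [t.commodity_code for t in translation],
            "percent": [t.percent for t in translation],
        }
    )
    if cons.empty:
        empty = cons.assign(commodity_code=pd.Series(dtype=str)).drop(
            columns=["food_code"]
        )
        return TranslatedConsumption(table=empty, untranslated=())

    known = set(trans["food_code"]) if not trans.empty else set()
    untranslated = tuple(sorted(set(cons["food_code"]) - known))

    merged = cons.merge(trans, on="food_code", how="inner")
    merged["amount"] = merged["amount"] * merged["percent"] / 100.0
    table = merged[
        ["subject_id", "day", "commodity_code", "amount", "body_weight",
         "survey_weight"]
    ].reset_index(drop=True)
    return TranslatedConsumption(table=table, untranslated=untranslated)


def daily_intake(
    commodity_amounts: Mapping[str, float],
    concentrations: Mapping[str, float],
    body_weight: float,
) -> float:
    """Intake for one subject-day, in ug/kg bw/day.

    ``commodity_amounts`` holds g/day of each raw commodity eaten that day;
    ``concentrations`` holds resolved mg/kg per commodity (commodities
    without a concentration contribute nothing).
    """
    if body_weight <= 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    total_ug = 0.0
    for commodity, grams in commodity_amounts.items():
        if grams < 0:
            raise ValueError(f"negative amount for {commodity}: {grams}")
        conc = concentrations.get(commodity, 0.0)
        if conc < 0:
            raise ValueError(f"negative concentration for {commodity}: {conc}")
        total_ug += grams * conc  # g x mg/kg = ug
    return total_ug / body_weight


def oim(per_day_intakes: Sequence[float]) -> float:
    """Observed individual mean: average intake over a subject's recall days."""
    if len(per_day_intakes) == 0:
        raise ValueError("OIM requires at least one recall day")
    return float(np.mean(per_day_intakes))


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(weights * values) / np.sum(weights))


def weighted_quantile(values, weights, q: float) -> float:
    """Weighted quantile by linear interpolation over cumulative weights.

    Each sorted observation i is placed at normalized position
    p_i = (C_i - w_i) / (S - w_i), where C_i is the cumulative weight up
    to and including i and S the total weight; quantiles interpolate
    linearly between adjacent positions and clamp at the extremes. With
    equal weights this reduces exactly to the standard linear
    interpolation quantile (numpy's default).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must align")
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty set")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must lie in [0, 1], got {q}")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    total = np.sum(w)
    cum = np.cumsum(w)
    denom = total - w
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = np.where(denom > 0, (cum - w) / denom, 0.5)
    if v.size == 1:
        return float(v[0])
    return float(np.interp(q, pos, v))


def summarize(
    substance_code: str,
    scenario: Scenario,
    per_subject_oim: Mapping[str, float],
    survey_weights: Mapping[str, float],
) -> ExposureEstimate:
    """Survey-weighted population summary of per-subject OIM intakes."""
    subjects = sorted(per_subject_oim)
    if set(subjects) != set(survey_weights):
        raise ValueError("survey weights must cover exactly the OIM subjects")
    vals = np.array([per_subject_oim[s] for s in subjects], dtype=float)
    wts = np.array([survey_weights[s] for s in subjects], dtype=float)
    if np.any(wts <= 0):
        raise ValueError("survey weights must be positive")
    return ExposureEstimate(
        substance_code=substance_code,
        scenario=Scenario(scenario),
        per_subject_oim={s: float(per_subject_oim[s]) for s in subjects},
        weighted_mean=weighted_mean(vals, wts),
        weighted_median=weighted_quantile(vals, wts, 0.5),
        weighted_p95=weighted_quantile(vals, wts, 0.95),
        n_subjects=len(subjects),
    )


def compute_exposures(
    concentrations: Sequence[ConcentrationSample],
    consumption: Sequence[ConsumptionRecord],
    translation: Sequence[TranslationEntry],
    scenario: Scenario,
    substances: Sequence[str] | None = None,
) -> dict[str, ExposureEstimate]:
    """Full engine: per-substance OIM exposure summaries for one scenario.

    ``substances`` restricts (and pads) the output: substances with no
    measured samples get an all-zero exposure distribution. Every subject
    in the diary appears in every substance's distribution, with OIM = 0
    when none of their foods carries the substance.
    """
    scenario = Scenario(scenario)
    translated = translate_consumption(consumption, translation)
    table = translated.table

    subject_meta = {}
    for r in consumption:
        subject_meta[r.subject_id] = (r.body_weight, r.survey_weight)
    all_subjects = sorted(subject_meta)
    weights = {s: subject_meta[s][1] for s in all_subjects}
    days_per_subject = {
        s: sorted({r.day for r in consumption if r.subject_id == s})
        for s in all_subjects
    }

    pooled = mean_concentrations(concentrations, scenario)
    substance_codes = sorted(
        substances if substances is not None
        else {s.substance_code for s in concentrations}
    )

    if not table.empty:
        grouped = (
            table.groupby(["subject_id", "day", "commodity_code"], sort=False)[
                "amount"
            ].sum()
        )
    else:
        grouped = pd.Series(dtype=float)

    results: dict[str, ExposureEstimate] = {}
    for code in substance_codes:
        conc_by_commodity = {
            commodity: conc
            for (subst, commodity), conc in pooled.items()
            if subst == code
        }
        per_subject: dict[str, float] = {}
        if conc_by_commodity and not table.empty:
            mask = table["commodity_code"].isin(conc_by_commodity)
            sub = table.loc[mask].copy()
            if not sub.empty:
                sub["conc"] = sub["commodity_code"].map(conc_by_commodity)
                sub["ug"] = sub["amount"] * sub["conc"]
                day_ug = sub.groupby(["subject_id", "day"])["ug"].sum()
                for subject in day_ug.index.get_level_values(0).unique():
                    bw = subject_meta[subject][0]
                    intakes = [
                        float(day_ug.get((subject, d), 0.0)) / bw
                        for d in days_per_subject[subject]
                    ]
                    per_subject[subject] = oim(intakes)
        for subject in all_subjects:
            per_subject.setdefault(subject, 0.0)
        results[code] = summarize(code, scenario, per_subject, weights)
    return results


def exposures_to_frame(estimates: Mapping[str, ExposureEstimate]) -> pd.DataFrame:
    """Tabular summary view, one row per substance."""
    rows = [
        {
            "substance_code": est.substance_code,
            "scenario": est.scenario.value,
            "weighted_mean": est.weighted_mean,
            "weighted_median": est.weighted_median,
            "weighted_p95": est.weighted_p95,
            "n_subjects": est.n_subjects,
        }
        for _, est in sorted(estimates.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["substance_code", "scenario", "weighted_mean",
                 "weighted_median", "weighted_p95", "n_subjects"],
    )
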