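"""Seeded generators for the five input tables, with known ground truth.

The generators emulate the statistical shape of the real inputs — a
multi-country concentration-monitoring database, a two-recall-day
national consumption survey, a food-to-commodity translation table,
substance annotations and heterogeneous HTS result tables — at desk
scale, so that every downstream stage can be tested end-to-end without
any external data.

Each synthetic substance is *planted* on one decision-tree branch
(excluded / genotoxic / organophosphate / carbamate / Cramer I-III /
no structure) and one exposure tier (high: mean exposure 20x its
threshold; low: 0.02x), and the generator records the intended branch
and priority-list membership in a truth table. Plant realizability is
asserted at generation time — the generated annotation is run through
the decision tree and must land on its planted branch — so downstream
test failures always indicate pipeline bugs, not generator bugs.

Distribution choices: concentrations are log-normal and consumption
amounts gamma-distributed (the standard right-skewed models for residue
and intake data); survey weights are uniform in [0.5, 2] and normalized
to mean 1; body weights are truncated normal around 70 kg. Exactly two
recall days per subject by default, matching the survey design the
pipeline targets.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ngra import io as ngio
from ngra import ttc as ttc_engine
from ngra.exposure import translate_consumption
from ngra.model import (
    AlertProfile,
    ALERT_FIELDS,
    CLASS_SUFFIXES,
    ConcentrationSample,
    ConsumptionRecord,
    CramerClass,
    ExclusionFlag,
    HtsRawRecord,
    HtsStatus,
    ReadoutType,
    ResultType,
    SubstanceAnnotation,
    TranslationEntry,
    TtcOutcome,
)
from ngra.prioritize import DEFAULT_EXCLUDED_CUTOFF


class PlantRealizabilityError(RuntimeError):
    """A planted design cannot be realized by the generated tables."""


class PlantBranch(str, enum.Enum):
    excluded = "excluded"
    genotoxic = "genotoxic"
    op_phosphate = "op_phosphate"
    carbamate = "carbamate"
    cramer_I = "cramer_I"
    cramer_II = "cramer_II"
    cramer_III = "cramer_III"
    no_structure = "no_structure"


class ExposureTier(str, enum.Enum):
    high = "high"  # planted mean exposure 20x the branch threshold
    low = "low"    # 0.02x


#: TTC the branch leads to (None where no threshold applies).
BRANCH_TTC: dict[PlantBranch, Optional[float]] = {
    PlantBranch.excluded: None,
    PlantBranch.genotoxic: ttc_engine.TTC_GENOTOXIC,
    PlantBranch.op_phosphate: ttc_engine.TTC_OP_CARBAMATE,
    PlantBranch.carbamate: ttc_engine.TTC_OP_CARBAMATE,
    PlantBranch.cramer_I: 30.0,
    PlantBranch.cramer_II: 9.0,
    PlantBranch.cramer_III: 1.5,
    PlantBranch.no_structure: None,
}

#: Reference level the exposure tier multiplies: the TTC where one exists,
#: the excluded-list cutoff for excluded substances, and an arbitrary
#: mid-range threshold for structure-less substances.
def _branch_reference_level(branch: PlantBranch) -> float:
    ttc = BRANCH_TTC[branch]
    if ttc is not None:
        return ttc
    if branch is PlantBranch.excluded:
        return DEFAULT_EXCLUDED_CUTOFF
    return 1.5


TIER_MULTIPLIER = {ExposureTier.high: 20.0, ExposureTier.low: 0.02}

_DEFAULT_BRANCH_CYCLE = (
    PlantBranch.genotoxic, PlantBranch.cramer_III, PlantBranch.excluded,
    PlantBranch.op_phosphate, PlantBranch.cramer_I, PlantBranch.no_structure,
    PlantBranch.carbamate, PlantBranch.cramer_II,
)


class PlantedSubstance(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: str
    branch: PlantBranch
    tier: ExposureTier


class SyntheticScenario(BaseModel):
    """Parameters of one synthetic study.

    The defaults are the study conditions used throughout the test
    suite: 200 subjects x 2 recall days, 14 substances spread over the
    five class suffixes, 30% non-detects.
    """

    model_config = ConfigDict(frozen=True)

    n_subjects: int = 200
    n_days: int = 2
    n_substances_per_class: dict[str, int] = Field(
        default_factory=lambda: {"PPP": 6, "ORG": 2, "TOX": 2, "CHE": 2, "PAR": 2}
    )
    n_foods: int = 12
    n_commodities: int = 9
    nondetect_fraction: float = 0.3
    n_samples_per_commodity: int = 10
    concentration_sigma: float = 0.4  # sigma of log mg/kg around the target
    hts_not_tested_fraction: float = 0.2
    planted: Optional[tuple[PlantedSubstance, ...]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "SyntheticScenario":
        for name in ("n_subjects", "n_days", "n_foods", "n_commodities",
                     "n_samples_per_commodity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.nondetect_fraction <= 1.0:
            raise ValueError("nondetect_fraction must lie in [0, 1]")
        if not 0.0 <= self.hts_not_tested_fraction <= 1.0:
            raise ValueError("hts_not_tested_fraction must lie in [0, 1]")
        bad = [c for c in self.n_substances_per_class if c not in CLASS_SUFFIXES]
        if bad:
            raise ValueError(f"unknown class suffix(es) {bad}")
        if any(n < 1 for n in self.n_substances_per_class.values()):
            raise ValueError("substance counts must be >= 1")
        return self

    def planted_substances(self) -> tuple[PlantedSubstance, ...]:
        """The explicit plant list, or the default round-robin design."""
        if self.planted is not None:
            return self.planted
        plants = []
        i = 0
        for suffix in CLASS_SUFFIXES:
            for k in range(self.n_substances_per_class.get(suffix, 0)):
                plants.append(
                    PlantedSubstance(
                        code=f"RF-{i + 1:04d}-{suffix}",
                        branch=_DEFAULT_BRANCH_CYCLE[i % len(_DEFAULT_BRANCH_CYCLE)],
                        tier=(ExposureTier.high if i % 2 == 0 else ExposureTier.low),
                    )
                )
                i += 1
        return tuple(plants)


@dataclass
class ScenarioBundle:
    """All generated tables plus the planted ground truth."""

    params: SyntheticScenario
    seed: int
    concentrations: list[ConcentrationSample]
    consumption: list[ConsumptionRecord]
    translation: list[TranslationEntry]
    annotations: list[SubstanceAnnotation]
    hts_tables: dict[str, list[HtsRawRecord]]
    truth: pd.DataFrame = field(repr=False)

    def write(self, out_dir) -> dict[str, Path]:
        """Write the five input tables plus truth_table.csv; byte-deterministic."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ngio.write_concentration_table(self.concentrations,
                                       out_dir / "concentrations.csv")
        ngio.write_consumption_table(self.consumption, out_dir / "consumption.csv")
        ngio.write_translation_table(self.translation, out_dir / "translation.csv")
        ngio.write_annotations(self.annotations, out_dir / "annotations.csv")
        written = {
            "concentrations.csv": out_dir / "concentrations.csv",
            "consumption.csv": out_dir / "consumption.csv",
            "translation.csv": out_dir / "translation.csv",
            "annotations.csv": out_dir / "annotations.csv",
        }
        for model_id in sorted(self.hts_tables):
            fname = f"hts_{model_id}.csv"
            ngio.write_hts_table(self.hts_tables[model_id], out_dir / fname)
            written[fname] = out_dir / fname
        self.truth.to_csv(out_dir / "truth_table.csv", index=False)
        written["truth_table.csv"] = out_dir / "truth_table.csv"
        return written


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

_ALKYL = ("C", "CC", "CCC", "CC(C)C", "CCCC")
_ARYL = ("c1ccccc1", "c1ccc(C)cc1")

# Molecules guaranteed to avoid both substructure patterns even in
# relaxed mode (no phosphorus; no O-C(=O)-N motif).
_NEITHER_TEMPLATES = (
    "CCO", "CC(C)O", "c1ccccc1", "CCCCCC", "CC(=O)OCC", "CCN(CC)CC",
    "CCOCC", "CC(C)C(=O)O", "c1ccc2ccccc2c1", "CC(=O)Nc1ccccc1",
)


def generate_structures(branch: str, rng: Optional[np.random.Generator] = None) -> str:
    """Return a SMILES that provably matches (or avoids) the step-3 patterns.

    ``branch`` is one of ``op_phosphate`` (matches the literal phosphate
    pattern), ``carbamate_disubstituted`` (matches the literal carbamate
    pattern) or ``neither`` (avoids both patterns even in relaxed mode).
    Structures are assembled from curated templates with randomized
    substituents; membership is asserted before returning.
    """
    rng = rng or np.random.default_rng(0)
    if branch == "op_phosphate":
        r1, r2, r3 = (str(rng.choice(_ALKYL)) for _ in range(3))
        smiles = f"O=P(O{r1})(O{r2})O{r3}"
        hits = ttc_engine.match_op_carbamate(smiles, ttc_engine.SubstructureMode.literal)
        assert hits.phosphate_hit, smiles
        return smiles
    if branch == "carbamate_disubstituted":
        r1 = str(rng.choice(_ALKYL + _ARYL))
        r2, r3 = (str(rng.choice(_ALKYL)) for _ in range(2))
        smiles = f"O({r1})C(=O)N({r2}){r3}"
        hits = ttc_engine.match_op_carbamate(smiles, ttc_engine.SubstructureMode.literal)
        assert hits.carbamate_hit, smiles
        return smiles
    if branch == "neither":
        smiles = str(rng.choice(_NEITHER_TEMPLATES))
        hits = ttc_engine.match_op_carbamate(smiles, ttc_engine.SubstructureMode.relaxed)
        assert not hits.any, smiles
        return smiles
    raise ValueError(f"unknown structure branch {branch!r}")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ENDPOINT_FIELDS = {
    "ames": ("derek_ames", "iss_ames", "oasis_ames"),
    "chromosome_damage": (
        "derek_chromosome_damage", "iss_chromosome_damage",
        "oasis_chromosome_damage",
    ),
}


def _alerts_without_consensus(rng: np.random.Generator) -> AlertProfile:
    """At most one positive model per endpoint: never reaches 2-of-3."""
    bools = dict.fromkeys(ALERT_FIELDS, False)
    for fields in _ENDPOINT_FIELDS.values():
        if rng.random() < 0.4:
            bools[str(rng.choice(fields))] = True
    return AlertProfile(**bools)


def _alerts_with_consensus(rng: np.random.Generator) -> AlertProfile:
    """At least two positive models on one endpoint."""
    bools = dict.fromkeys(ALERT_FIELDS, False)
    endpoint = str(rng.choice(sorted(_ENDPOINT_FIELDS)))
    fields = _ENDPOINT_FIELDS[endpoint]
    n_pos = int(rng.integers(2, 4))
    for f in rng.choice(fields, size=n_pos, replace=False):
        bools[str(f)] = True
    other = next(k for k in _ENDPOINT_FIELDS if k != endpoint)
    if rng.random() < 0.3:
        bools[str(rng.choice(_ENDPOINT_FIELDS[other]))] = True
    return AlertProfile(**bools)


def _make_annotation(
    plant: PlantedSubstance, rng: np.random.Generator
) -> SubstanceAnnotation:
    branch = plant.branch
    if branch is PlantBranch.no_structure:
        return SubstanceAnnotation(code=plant.code, name=f"synthetic {plant.code}")
    if branch is PlantBranch.excluded:
        n_flags = int(rng.integers(1, 3))
        flags = frozenset(
            ExclusionFlag(str(f))
            for f in rng.choice([f.value for f in ExclusionFlag],
                                size=n_flags, replace=False)
        )
        smiles = (
            generate_structures("neither", rng) if rng.random() < 0.5 else None
        )
        return SubstanceAnnotation(
            code=plant.code, name=f"synthetic {plant.code}",
            smiles=smiles, exclusion_flags=flags,
        )
    if branch is PlantBranch.genotoxic:
        smiles = generate_structures("neither", rng)
        alerts = _alerts_with_consensus(rng)
        cramer = CramerClass(str(rng.choice([c.value for c in CramerClass])))
    elif branch is PlantBranch.op_phosphate:
        smiles = generate_structures("op_phosphate", rng)
        alerts = _alerts_without_consensus(rng)
        cramer = CramerClass.III
    elif branch is PlantBranch.carbamate:
        smiles = generate_structures("carbamate_disubstituted", rng)
        alerts = _alerts_without_consensus(rng)
        cramer = CramerClass.III
    else:
        smiles = generate_structures("neither", rng)
        alerts = _alerts_without_consensus(rng)
        cramer = {
            PlantBranch.cramer_I: CramerClass.I,
            PlantBranch.cramer_II: CramerClass.II,
            PlantBranch.cramer_III: CramerClass.III,
        }[branch]
    return SubstanceAnnotation(
        code=plant.code, name=f"synthetic {plant.code}", smiles=smiles,
        alerts=alerts, cramer_class=cramer,
    )


def _assert_plant_realized(plant: PlantedSubstance,
                           annotation: SubstanceAnnotation) -> None:
    assignment = ttc_engine.assign_ttc(annotation,
                                       ttc_engine.SubstructureMode.literal)
    branch = plant.branch
    if branch is PlantBranch.excluded:
        ok = assignment.outcome is TtcOutcome.excluded
    elif branch is PlantBranch.no_structure:
        ok = assignment.outcome is TtcOutcome.no_structure
    else:
        ok = (
            assignment.outcome is TtcOutcome.ttc_assigned
            and assignment.ttc_value == BRANCH_TTC[branch]
        )
    if not ok:
        raise PlantRealizabilityError(
            f"substance {plant.code}: planted branch {branch.value} but the "
            f"decision tree returned {assignment.outcome.value} "
            f"(ttc={assignment.ttc_value})"
        )


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def generate_scenario(
    params: SyntheticScenario, seed: Optional[int] = None
) -> ScenarioBundle:
    """Generate all five input tables plus the ground-truth table.

    Deterministic given ``(params, seed)`` (``seed`` overrides
    ``params.seed`` when given). The planted exposure tier is calibrated
    against the *realized* consumption: for each substance the generator
    measures the survey-weighted mean commodity intake per kg body weight
    and sets the concentration level so the expected upper-bound mean
    exposure is 20x (high tier) or 0.02x (low tier) the branch's
    reference threshold. A plant whose measured commodities nobody
    consumes raises :class:`PlantRealizabilityError`.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    plants = params.planted_substances()
    codes = [p.code for p in plants]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate substance codes in the planted design")

    commodities = [f"C{i + 1:03d}" for i in range(params.n_commodities)]
    foods = [f"F{i + 1:03d}" for i in range(params.n_foods)]

    # Translation: every commodity reachable from >= 1 food and every food
    # mapping to >= 1 commodity, plus random extra links (1-3 per food).
    links: set[tuple[str, str]] = set()
    for i, commodity in enumerate(commodities):
        links.add((foods[i % params.n_foods], commodity))
    for food in foods:
        have = sum(1 for f, _ in links if f == food)
        want = int(rng.integers(1, 4))
        extra = max(0, want - have)
        if have == 0:
            extra = max(extra, 1)
        for c in rng.choice(commodities, size=min(extra, len(commodities)),
                            replace=False):
            links.add((food, str(c)))
    translation = [
        TranslationEntry(food_code=f, commodity_code=c,
                         percent=float(rng.integers(20, 101)))
        for f, c in sorted(links)
    ]

    # Subjects and diary.
    subject_ids = [f"S{i + 1:05d}" for i in range(params.n_subjects)]
    body_weights = np.clip(rng.normal(70.0, 12.0, params.n_subjects), 40.0, 120.0)
    survey_weights = rng.uniform(0.5, 2.0, params.n_subjects)
    survey_weights = survey_weights / survey_weights.mean()
    consumption: list[ConsumptionRecord] = []
    max_foods_per_day = min(5, params.n_foods)
    for i, subject in enumerate(subject_ids):
        for day in range(1, params.n_days + 1):
            n_eat = int(rng.integers(2, max_foods_per_day + 1)) \
                if max_foods_per_day >= 2 else 1
            eaten = rng.choice(foods, size=n_eat, replace=False)
            amounts = rng.gamma(2.0, 60.0, size=n_eat)
            for food, amount in zip(eaten, amounts):
                consumption.append(
                    ConsumptionRecord(
                        subject_id=subject, day=day, food_code=str(food),
                        amount=float(round(amount, 3)),
                        body_weight=float(round(body_weights[i], 2)),
                        survey_weight=float(survey_weights[i]),
                    )
                )

    # Realized survey-weighted intake factor per commodity set:
    # K = weighted_mean_i [ (sum_c total_amount_ic / n_days) / bw_i ]  (g/day/kg)
    translated = translate_consumption(consumption, translation).table
    per_subject_commodity = (
        translated.groupby(["subject_id", "commodity_code"])["amount"].sum()
    )
    bw_by_subject = {r.subject_id: r.body_weight for r in consumption}
    sw_by_subject = {r.subject_id: r.survey_weight for r in consumption}

    def intake_factor(commodity_set: Sequence[str]) -> float:
        total_w = 0.0
        acc = 0.0
        for subject in subject_ids:
            grams = sum(
                float(per_subject_commodity.get((subject, c), 0.0))
                for c in commodity_set
            )
            k_i = grams / params.n_days / bw_by_subject[subject]
            acc += sw_by_subject[subject] * k_i
            total_w += sw_by_subject[subject]
        return acc / total_w

    # Concentrations, calibrated per plant.
    concentrations: list[ConcentrationSample] = []
    truth_rows = []
    annotations: list[SubstanceAnnotation] = []
    for plant in plants:
        annotation = _make_annotation(plant, rng)
        _assert_plant_realized(plant, annotation)
        annotations.append(annotation)

        n_meas = int(rng.integers(1, min(3, params.n_commodities) + 1))
        measured = sorted(
            str(c) for c in rng.choice(commodities, size=n_meas, replace=False)
        )
        factor = intake_factor(measured)
        reference = _branch_reference_level(plant.branch)
        target = reference * TIER_MULTIPLIER[plant.tier]
        if factor <= 0:
            raise PlantRealizabilityError(
                f"substance {plant.code}: measured commodities {measured} are "
                f"never consumed; planted exposure tier cannot be realized"
            )
        level = target / factor  # mg/kg giving the target mean exposure
        sigma = params.concentration_sigma
        mu = math.log(level) - 0.5 * sigma * sigma  # arithmetic mean = level
        lod = 0.6 * level
        loq = 1.2 * level
        for commodity in measured:
            values = rng.lognormal(mu, sigma, params.n_samples_per_commodity)
            censored = rng.random(params.n_samples_per_commodity) \
                < params.nondetect_fraction
            lod_side = rng.random(params.n_samples_per_commodity) < 0.5
            for v, is_cens, at_lod in zip(values, censored, lod_side):
                if is_cens:
                    concentrations.append(
                        ConcentrationSample(
                            substance_code=plant.code, commodity_code=commodity,
                            result_type=(ResultType.ND_LOD if at_lod
                                         else ResultType.ND_LOQ),
                            lod=lod, loq=loq,
                        )
                    )
                else:
                    concentrations.append(
                        ConcentrationSample(
                            substance_code=plant.code, commodity_code=commodity,
                            result_type=ResultType.VAL,
                            value=float(v), lod=lod, loq=loq,
                        )
                    )

        if plant.branch is PlantBranch.no_structure:
            expected_outcome, expected_ttc = TtcOutcome.no_structure, None
            expected_list = "unevaluated"
        elif plant.branch is PlantBranch.excluded:
            expected_outcome, expected_ttc = TtcOutcome.excluded, None
            expected_list = (
                "ttc_excluded_priority"
                if plant.tier is ExposureTier.high else "not_priority"
            )
        else:
            expected_outcome = TtcOutcome.ttc_assigned
            expected_ttc = BRANCH_TTC[plant.branch]
            expected_list = (
                "ttc_priority" if plant.tier is ExposureTier.high
                else "not_priority"
            )
        truth_rows.append(
            {
                "substance_code": plant.code,
                "branch": plant.branch.value,
                "tier": plant.tier.value,
                "expected_outcome": expected_outcome.value,
                "expected_ttc": "" if expected_ttc is None else expected_ttc,
                "expected_list": expected_list,
                "target_mean_exposure": target,
                "concentration_level": level,
                "measured_commodities": ";".join(measured),
            }
        )

    truth = pd.DataFrame(truth_rows)

    # HTS tables from a planted potency order over the structured substances.
    structured = [a.code for a in annotations if a.smiles is not None]
    order = [str(c) for c in rng.permutation(structured)]
    hts_tables = generate_hts_tables(
        codes, order, rng, not_tested_fraction=params.hts_not_tested_fraction
    )
    truth["hts_potency_rank"] = [
        (order.index(c) + 1 if c in order else "") for c in truth["substance_code"]
    ]

    return ScenarioBundle(
        params=params, seed=seed, concentrations=concentrations,
        consumption=consumption, translation=translation,
        annotations=annotations, hts_tables=hts_tables, truth=truth,
    )


def generate_hts_tables(
    substances: Sequence[str],
    planted_potency_order: Sequence[str],
    rng: np.random.Generator | int,
    not_tested_fraction: float = 0.2,
) -> dict[str, list[HtsRawRecord]]:
    """One synthetic table per readout type, monotone in the planted order.

    ``planted_potency_order`` ranks a subset of ``substances`` from most to
    least potent. Within each table the raw values are monotone-consistent
    with that order: AC50/LEL increase down the ranking (less potent =
    higher active concentration) while composite scores, percentages and
    reversed ranks decrease. A ``not_tested_fraction`` of substances per
    table is marked untested (distinct from inactive); substances outside
    the planted order are inactive.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    order = list(planted_potency_order)
    if len(order) != len(set(order)):
        raise ValueError("planted potency order must be a strict ranking")
    unknown = [c for c in order if c not in set(substances)]
    if unknown:
        raise ValueError(f"planted order contains unknown substance(s) {unknown}")

    tables: dict[str, list[HtsRawRecord]] = {}
    for readout in ReadoutType:
        model_id = f"model_{readout.value}"
        untested = {
            c for c in substances if rng.random() < not_tested_fraction
        }
        actives = [c for c in order if c not in untested]
        n = len(actives)
        if readout in (ReadoutType.composite_score, ReadoutType.percent):
            lo, hi = (0.05, 1.0) if readout is ReadoutType.composite_score \
                else (5.0, 100.0)
            vals = np.sort(rng.uniform(lo, hi, n))[::-1]  # decreasing = less potent
        elif readout in (ReadoutType.ac50, ReadoutType.lel):
            vals = np.sort(10.0 ** rng.uniform(-2.0, 3.0, n))  # uM, increasing
        else:  # rank
            vals = np.arange(1, n + 1, dtype=float)
        value_by_code = {c: float(v) for c, v in zip(actives, vals)}

        records = []
        for code in substances:
            if code in untested:
                records.append(
                    HtsRawRecord(model_id=model_id, substance_code=code,
                                 readout_type=readout,
                                 status=HtsStatus.not_tested)
                )
            elif code in value_by_code:
                records.append(
                    HtsRawRecord(model_id=model_id, substance_code=code,
                                 readout_type=readout,
                                 value=value_by_code[code],
                                 status=HtsStatus.active)
                )
            else:
                records.append(
                    HtsRawRecord(model_id=model_id, substance_code=code,
                                 readout_type=readout,
                                 status=HtsStatus.not_active)
                )
        tables[model_id] = records
    return tables
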