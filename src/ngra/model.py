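"""Domain types shared across the prioritization pipeline.

The pipeline moves five kinds of records between stages: analytical
concentration measurements (possibly left-censored at LOD/LOQ),
consumption-diary entries, food-to-commodity translation entries,
substance annotations (structure, exclusion flags, genotoxicity alert
profile, Cramer class), and raw high-throughput-screening readouts.
Every record is validated on construction so downstream stages can rely
on the invariants instead of re-checking them.
"""

from __future__ import annotations

import enum
import math
import re
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: The five substance-class suffixes carried by substance codes:
#: pesticides (PPP), organic contaminants (ORG), toxins (TOX), other
#: chemicals in food such as metals and nitrates (CHE), miscellaneous (PAR).
CLASS_SUFFIXES = ("PPP", "ORG", "TOX", "CHE", "PAR")

_CODE_RE = re.compile(r"^.+-(" + "|".join(CLASS_SUFFIXES) + r")$")


class Scenario(str, enum.Enum):
    """Left-censoring substitution convention for non-detects."""

    lower_bound = "lower_bound"  # non-detects treated as absent (0)
    upper_bound = "upper_bound"  # non-detects set to their LOD / LOQ


class ResultType(str, enum.Enum):
    VAL = "VAL"          # quantified value
    ND_LOD = "ND_LOD"    # below the limit of detection
    ND_LOQ = "ND_LOQ"    # below the limit of quantification


class CramerClass(str, enum.Enum):
    I = "I"      # low structural toxicity concern
    II = "II"    # intermediate
    III = "III"  # high


class ExclusionFlag(str, enum.Enum):
    """Categories for which no safe exposure threshold can be derived."""

    inorganic = "inorganic"
    metal_containing = "metal_containing"
    mixture = "mixture"
    bioaccumulating = "bioaccumulating"
    aflatoxin_like = "aflatoxin_like"


class TtcOutcome(str, enum.Enum):
    excluded = "excluded"
    ttc_assigned = "ttc_assigned"
    no_structure = "no_structure"


class PriorityList(str, enum.Enum):
    ttc_priority = "ttc_priority"                    # TTC assigned and HQ > 1
    ttc_excluded_priority = "ttc_excluded_priority"  # excluded, exposure >= cutoff
    not_priority = "not_priority"
    unevaluated = "unevaluated"                      # no structure available


class ReadoutType(str, enum.Enum):
    composite_score = "composite_score"  # e.g. ToxPi-style aggregate, dimensionless
    percent = "percent"                  # percentage activity
    ac50 = "ac50"                        # 50% active concentration, uM
    rank = "rank"                        # position in an ordered potency list
    lel = "lel"                          # lowest effect level, uM


class HtsStatus(str, enum.Enum):
    active = "active"
    not_active = "not_active"
    not_tested = "not_tested"


def substance_class(code: str) -> str:
    """Return the class suffix of a substance code, e.g. ``RF-0001-PPP`` -> ``PPP``."""
    m = _CODE_RE.match(code)
    if m is None:
        raise ValueError(
            f"substance code {code!r} lacks a class suffix in {CLASS_SUFFIXES}"
        )
    return m.group(1)


class AlertProfile(BaseModel):
    """Six genotoxicity alert booleans: three models x two endpoints.

    The models are DEREK Nexus, the ISS profilers and the OASIS profilers;
    the endpoints are Ames (bacterial) mutagenicity and chromosome damage.
    Absence of an evaluation is modelled by an absent profile on the
    annotation, never by a missing boolean here.
    """

    model_config = ConfigDict(frozen=True)

    derek_ames: bool
    iss_ames: bool
    oasis_ames: bool
    derek_chromosome_damage: bool
    iss_chromosome_damage: bool
    oasis_chromosome_damage: bool

    def ames_votes(self) -> int:
        return int(self.derek_ames) + int(self.iss_ames) + int(self.oasis_ames)

    def chromosome_damage_votes(self) -> int:
        return (
            int(self.derek_chromosome_damage)
            + int(self.iss_chromosome_damage)
            + int(self.oasis_chromosome_damage)
        )

    @classmethod
    def all_negative(cls) -> "AlertProfile":
        return cls(
            derek_ames=False, iss_ames=False, oasis_ames=False,
            derek_chromosome_damage=False, iss_chromosome_damage=False,
            oasis_chromosome_damage=False,
        )


ALERT_FIELDS = (
    "derek_ames", "iss_ames", "oasis_ames",
    "derek_chromosome_damage", "iss_chromosome_damage", "oasis_chromosome_damage",
)


class SubstanceAnnotation(BaseModel):
    """Identity, structure and hazard annotations for one substance.

    ``smiles`` is either a valid SMILES string or ``None`` ("no structure";
    the substance then bypasses the decision tree and lands in the
    unevaluated list). ``cramer_class`` and ``alerts`` are inputs produced
    by external profilers; completeness for the decision tree is checked
    when the tree runs, since excluded or structure-less substances may
    legitimately lack them.
    """

    model_config = ConfigDict(frozen=True)

    code: str
    name: str = ""
    smiles: Optional[str] = None
    exclusion_flags: frozenset[ExclusionFlag] = frozenset()
    alerts: Optional[AlertProfile] = None
    cramer_class: Optional[CramerClass] = None

    @field_validator("code")
    @classmethod
    def _code_has_class_suffix(cls, v: str) -> str:
        substance_class(v)
        return v

    @field_validator("smiles")
    @classmethod
    def _smiles_parses(cls, v: Optional[str]) -> Optional[str]:
        if v is None:
            return v
        from ngra.io import parse_smiles  # deferred: RDKit import is heavy

        if parse_smiles(v) is None:
            raise ValueError(f"invalid SMILES: {v!r}")
        return v


class ConcentrationSample(BaseModel):
    """One analytical measurement of one substance in one raw commodity.

    Units are mg substance per kg commodity throughout. A quantified
    result carries ``value``; a censored result carries the relevant
    limit instead.
    """

    model_config = ConfigDict(frozen=True)

    substance_code: str
    commodity_code: str
    result_type: ResultType
    value: Optional[float] = None   # mg/kg, present iff VAL
    lod: Optional[float] = None     # mg/kg
    loq: Optional[float] = None     # mg/kg

    @field_validator("substance_code")
    @classmethod
    def _code_has_class_suffix(cls, v: str) -> str:
        substance_class(v)
        return v

    @model_validator(mode="after")
    def _censoring_consistent(self) -> "ConcentrationSample":
        if self.result_type is ResultType.VAL:
            if self.value is None:
                raise ValueError("VAL sample requires a value")
            if self.value < 0 or not math.isfinite(self.value):
                raise ValueError(f"value must be finite and >= 0, got {self.value}")
        elif self.value is not None:
            raise ValueError(f"{self.result_type.value} sample must not carry a value")
        if self.result_type is ResultType.ND_LOD and self.lod is None:
            raise ValueError("ND_LOD sample requires lod")
        if self.result_type is ResultType.ND_LOQ and self.loq is None:
            raise ValueError("ND_LOQ sample requires loq")
        for lim_name in ("lod", "loq"):
            lim = getattr(self, lim_name)
            if lim is not None and (lim <= 0 or not math.isfinite(lim)):
                raise ValueError(f"{lim_name} must be finite and > 0, got {lim}")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError(f"lod {self.lod} exceeds loq {self.loq}")
        return self


class ConsumptionRecord(BaseModel):
    """One consumed food reported by one survey subject on one recall day."""

    model_config = ConfigDict(frozen=True)

    subject_id: str
    day: int
    food_code: str
    amount: float         # g/day
    body_weight: float    # kg
    survey_weight: float  # post-stratification weight, positive

    @model_validator(mode="after")
    def _positive(self) -> "ConsumptionRecord":
        if self.amount < 0:
            raise ValueError(f"amount must be >= 0, got {self.amount}")
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if self.survey_weight <= 0:
            raise ValueError(f"survey_weight must be > 0, got {self.survey_weight}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        return self


class TranslationEntry(BaseModel):
    """Fraction (in %) of a consumed food attributed to one raw commodity.

    Percentages may exceed 100 for concentrated foods (e.g. dried fruit).
    """

    model_config = ConfigDict(frozen=True)

    food_code: str
    commodity_code: str
    percent: float  # % of consumed mass, > 0, may exceed 100

    @field_validator("percent")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0 or not math.isfinite(v):
            raise ValueError(f"percent must be finite and > 0, got {v}")
        return v


class HtsRawRecord(BaseModel):
    """One prediction model's raw readout for one substance."""

    model_config = ConfigDict(frozen=True)

    model_id: str
    substance_code: str
    readout_type: ReadoutType
    value: Optional[float] = None
    status: HtsStatus

    @model_validator(mode="after")
    def _value_matches_status(self) -> "HtsRawRecord":
        if self.status is HtsStatus.active:
            if self.value is None:
                raise ValueError("active record requires a value")
            if not math.isfinite(self.value):
                raise ValueError(f"value must be finite, got {self.value}")
            if self.readout_type in (ReadoutType.ac50, ReadoutType.lel):
                if self.value <= 0:
                    raise ValueError(
                        f"{self.readout_type.value} must be > 0, got {self.value}"
                    )
            if self.readout_type is ReadoutType.rank:
                if self.value < 1 or self.value != int(self.value):
                    raise ValueError(f"rank must be a positive integer, got {self.value}")
        elif self.value is not None:
            raise ValueError(f"{self.status.value} record must not carry a value")
        return self


class TtcAssignment(BaseModel):
    """Outcome of the four-step decision tree for one substance.

    ``decision_path`` records each step actually evaluated, in order,
    stopping at the first step that fires.
    """

    model_config = ConfigDict(frozen=True)

    substance_code: str
    outcome: TtcOutcome
    ttc_value: Optional[float] = None  # ug/kg bw/day, present iff ttc_assigned
    decision_path: tuple[str, ...] = ()
    exclusion_reason: Optional[str] = None

    @model_validator(mode="after")
    def _consistent(self) -> "TtcAssignment":
        if (self.ttc_value is not None) != (self.outcome is TtcOutcome.ttc_assigned):
            raise ValueError("ttc_value present iff outcome is ttc_assigned")
        if self.outcome is TtcOutcome.excluded and not self.exclusion_reason:
            raise ValueError("excluded outcome requires an exclusion_reason")
        return self


class ExposureEstimate(BaseModel):
    """Per-substance population summary of per-subject chronic intakes.

    Intakes follow the observed-individual-mean (OIM) model: each
    subject's daily intakes are averaged over their recall days, and the
    population summary is weighted by the survey weights. All values are
    ug substance per kg body weight per day.
    """

    model_config = ConfigDict(frozen=True)

    substance_code: str
    scenario: Scenario
    per_subject_oim: dict[str, float]
    weighted_mean: float
    weighted_median: float
    weighted_p95: float
    n_subjects: int

    def statistic(self, name: str) -> float:
        try:
            return {"mean": self.weighted_mean,
                    "median": self.weighted_median,
                    "p95": self.weighted_p95}[name]
        except KeyError:
            raise ValueError(f"unknown exposure statistic {name!r}") from None


class PriorityRecord(BaseModel):
    """One substance's combined exposure / TTC / hazard-quotient verdict."""

    model_config = ConfigDict(frozen=True)

    substance_code: str
    exposure_stat: Optional[float] = None  # ug/kg bw/day
    ttc: TtcAssignment
    hq: Optional[float] = None             # exposure / TTC, dimensionless
    list: PriorityList

    @model_validator(mode="after")
    def _hq_iff_assigned(self) -> "PriorityRecord":
        if (self.hq is not None) != (self.ttc.outcome is TtcOutcome.ttc_assigned):
            raise ValueError("hq present iff a TTC was assigned")
        if self.hq is not None and self.hq < 0:
            raise ValueError(f"hq must be >= 0, got {self.hq}")
        return self


class HtsScore(BaseModel):
    """One model's raw, intermediate and normalized potency for one substance."""

    model_config = ConfigDict(frozen=True)

    model_id: str
    substance_code: str
    readout_type: ReadoutType
    raw: Optional[float] = None
    potency: Optional[float] = None      # monotone in toxicological potency
    normalized: Optional[float] = None   # 0..100, most potent in dataset = 100
    status: HtsStatus

    @model_validator(mode="after")
    def _normalized_iff_active(self) -> "HtsScore":
        if (self.normalized is not None) != (self.status is HtsStatus.active):
            raise ValueError("normalized present iff status is active")
        if self.normalized is not None and not (0.0 <= self.normalized <= 100.0):
            raise ValueError(f"normalized must lie in [0, 100], got {self.normalized}")
        return self
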