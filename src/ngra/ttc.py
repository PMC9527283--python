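"""Four-step threshold-of-toxicological-concern (TTC) decision tree.

For each substance with a representative structure the tree evaluates,
in strict order with short-circuiting:

1. exclusion criteria — inorganic, metal-containing, mixture,
   bioaccumulating or aflatoxin-like substances get no threshold;
2. genotoxicity — a two-of-three cross-model consensus (DEREK, ISS,
   OASIS) on either Ames mutagenicity or chromosome damage assigns the
   mutagenicity TTC of 0.0025 ug/kg bw/day;
3. organophosphate / carbamate functionality — a substructure match
   assigns 0.3 ug/kg bw/day;
4. Cramer class — III, II and I map to 1.5, 9 and 30 ug/kg bw/day.

The substructure patterns exist in two documented modes. The *literal*
mode matches exactly the published patterns: phosphate O=P(-O-R)(-O-R)-O-R
and carbamate R-O-C(=O)-N(-R)-R with every R a non-hydrogen substituent.
These literal patterns miss P=S organophosphates (e.g. dimethoate) and
N-H carbamates, both common among real pesticides, so a *relaxed* mode
additionally tolerates sulfur in place of the phosphate oxygens and a
single N-H in the carbamate. Literal hits are a strict subset of relaxed
hits.
"""

from __future__ import annotations

import enum
from typing import NamedTuple

from rdkit import Chem

from ngra.model import (
    AlertProfile,
    CramerClass,
    SubstanceAnnotation,
    TtcAssignment,
    TtcOutcome,
)

#: TTC thresholds in ug/kg bw/day, keyed by the decision-tree branch.
TTC_GENOTOXIC = 0.0025
TTC_OP_CARBAMATE = 0.3
TTC_BY_CRAMER = {CramerClass.III: 1.5, CramerClass.II: 9.0, CramerClass.I: 30.0}
TTC_VALUES = (TTC_GENOTOXIC, TTC_OP_CARBAMATE, 1.5, 9.0, 30.0)


class SubstructureMode(str, enum.Enum):
    literal = "literal"
    relaxed = "relaxed"


# Phosphate: doubly-bonded O on a P carrying three O-linked non-hydrogen
# substituents. The ester oxygens are required to have a non-H neighbour
# besides P, so free P-OH groups do not count as substituents.
SMARTS_PHOSPHATE_LITERAL = "[OX1]=[PX4]([OX2][!#1])([OX2][!#1])[OX2][!#1]"
# Relaxed: sulfur tolerated at any of the four oxygen positions, covering
# thiophosphates (P=S) and thioester linkages.
SMARTS_PHOSPHATE_RELAXED = (
    "[OX1,SX1]=[PX4]([OX2,SX2][!#1])([OX2,SX2][!#1])[OX2,SX2][!#1]"
)

# Carbamate: R-O-C(=O)-N(-R)-R. [NX3;H0] bonded to the carbonyl carbon has
# two further neighbours, both necessarily non-hydrogen.
SMARTS_CARBAMATE_LITERAL = "[!#1][OX2]C(=O)[NX3;H0]"
# Relaxed: one N-H tolerated (mono-substituted carbamates); NH2 still rejected.
SMARTS_CARBAMATE_RELAXED = "[!#1][OX2]C(=O)[NX3;H0,H1]"

PATTERNS = {
    SubstructureMode.literal: {
        "phosphate": SMARTS_PHOSPHATE_LITERAL,
        "carbamate": SMARTS_CARBAMATE_LITERAL,
    },
    SubstructureMode.relaxed: {
        "phosphate": SMARTS_PHOSPHATE_RELAXED,
        "carbamate": SMARTS_CARBAMATE_RELAXED,
    },
}

_COMPILED = {
    mode: {name: Chem.MolFromSmarts(smarts) for name, smarts in pats.items()}
    for mode, pats in PATTERNS.items()
}


class IncompleteAnnotationError(ValueError):
    """A structured, non-excluded substance lacks the annotations the tree needs."""


class SubstructureHits(NamedTuple):
    phosphate_hit: bool
    carbamate_hit: bool

    @property
    def any(self) -> bool:
        return self.phosphate_hit or self.carbamate_hit


def check_exclusion(annotation: SubstanceAnnotation) -> tuple[bool, str | None]:
    """Step 1: does any TTC exclusion category apply?

    Returns ``(excluded, reason)`` where *reason* lists every set flag.
    """
    if annotation.exclusion_flags:
        reason = ";".join(sorted(f.value for f in annotation.exclusion_flags))
        return True, reason
    return False, None


def genotoxicity_consensus(alerts: AlertProfile) -> bool:
    """Step 2: two-of-three cross-model consensus on either endpoint.

    An endpoint (Ames mutagenicity, chromosome damage) is positive when at
    least two of the three models flag it; the substance is genotoxic when
    either endpoint is positive.
    """
    return alerts.ames_votes() >= 2 or alerts.chromosome_damage_votes() >= 2


def match_op_carbamate(
    smiles: str, mode: SubstructureMode = SubstructureMode.literal
) -> SubstructureHits:
    """Step 3: test a structure against the phosphate and carbamate patterns."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    mode = SubstructureMode(mode)
    pats = _COMPILED[mode]
    return SubstructureHits(
        phosphate_hit=mol.HasSubstructMatch(pats["phosphate"]),
        carbamate_hit=mol.HasSubstructMatch(pats["carbamate"]),
    )


def assign_ttc(
    annotation: SubstanceAnnotation,
    mode: SubstructureMode = SubstructureMode.literal,
) -> TtcAssignment:
    """Run the full decision tree for one substance.

    Steps are evaluated strictly in order 1 -> 2 -> 3 -> 4 and the first
    step that fires determines the outcome; ``decision_path`` records the
    verdict of every step actually evaluated. Substances without a
    structure cannot enter the tree and get outcome ``no_structure``.

    Raises :class:`IncompleteAnnotationError` when a structured,
    non-excluded substance lacks an alert profile or (if it reaches step 4)
    a Cramer class.
    """
    path: list[str] = []

    excluded, reason = check_exclusion(annotation)
    if excluded:
        path.append(f"step1:excluded({reason})")
        return TtcAssignment(
            substance_code=annotation.code,
            outcome=TtcOutcome.excluded,
            decision_path=tuple(path),
            exclusion_reason=reason,
        )
    path.append("step1:not_excluded")

    if annotation.smiles is None:
        path.append("no_structure")
        return TtcAssignment(
            substance_code=annotation.code,
            outcome=TtcOutcome.no_structure,
            decision_path=tuple(path),
        )

    if annotation.alerts is None:
        raise IncompleteAnnotationError(
            f"substance {annotation.code}: structure present but no "
            f"genotoxicity alert profile"
        )
    if genotoxicity_consensus(annotation.alerts):
        path.append("step2:genotoxic")
        return TtcAssignment(
            substance_code=annotation.code,
            outcome=TtcOutcome.ttc_assigned,
            ttc_value=TTC_GENOTOXIC,
            decision_path=tuple(path),
        )
    path.append("step2:not_genotoxic")

    hits = match_op_carbamate(annotation.smiles, mode)
    if hits.any:
        kinds = [k for k, hit in
                 (("phosphate", hits.phosphate_hit), ("carbamate", hits.carbamate_hit))
                 if hit]
        path.append(f"step3:op_carbamate({'+'.join(kinds)})")
        return TtcAssignment(
            substance_code=annotation.code,
            outcome=TtcOutcome.ttc_assigned,
            ttc_value=TTC_OP_CARBAMATE,
            decision_path=tuple(path),
        )
    path.append("step3:no_op_carbamate")

    if annotation.cramer_class is None:
        raise IncompleteAnnotationError(
            f"substance {annotation.code}: reached Cramer step without a "
            f"Cramer class annotation"
        )
    cramer = annotation.cramer_class
    path.append(f"step4:cramer_{cramer.value}")
    return TtcAssignment(
        substance_code=annotation.code,
        outcome=TtcOutcome.ttc_assigned,
        ttc_value=TTC_BY_CRAMER[cramer],
        decision_path=tuple(path),
    )
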