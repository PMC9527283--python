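"""Hazard-quotient ranking, priority lists and the screening subset.

A substance's hazard quotient (HQ) is its exposure estimate divided by
its TTC. Substances partition into four disjoint lists:

* ``ttc_priority`` — TTC assigned and HQ strictly > 1;
* ``ttc_excluded_priority`` — TTC-excluded and exposure >= the cutoff
  (0.5 ug/kg bw/day by default, inclusive);
* ``unevaluated`` — no representative structure, awaiting further
  prioritization;
* ``not_priority`` — everything else.

From the ``ttc_priority`` list a fixed number of highest-HQ substances
per TTC class is selected for high-throughput screening; the default
counts are 10 for the genotoxicity class (0.0025) and 2 for each other
class.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from ngra.model import (
    ExposureEstimate,
    PriorityList,
    PriorityRecord,
    TtcAssignment,
    TtcOutcome,
)

#: Per-TTC-class screening counts: 10 / 2 / 2 for the classes represented
#: in the source study (0.0025, 0.3, 1.5), extended symmetrically with 2
#: for the 9 and 30 classes.
DEFAULT_CLASS_COUNTS: dict[float, int] = {0.0025: 10, 0.3: 2, 1.5: 2, 9.0: 2, 30.0: 2}

#: Exposure cutoff (ug/kg bw/day, inclusive) for TTC-excluded substances.
DEFAULT_EXCLUDED_CUTOFF = 0.5


def hazard_quotient(exposure_stat: float, ttc_value: float) -> float:
    """HQ = exposure / TTC (both in ug/kg bw/day, so dimensionless)."""
    if ttc_value <= 0:
        raise ValueError(f"ttc_value must be > 0, got {ttc_value}")
    if exposure_stat <= 0:
        raise ValueError(f"exposure_stat must be > 0, got {exposure_stat}")
    return exposure_stat / ttc_value


def build_lists(
    exposures: Mapping[str, ExposureEstimate] | Mapping[str, float],
    assignments: Sequence[TtcAssignment],
    cutoff: float = DEFAULT_EXCLUDED_CUTOFF,
    statistic: str = "mean",
) -> list[PriorityRecord]:
    """Partition all substances into the four priority lists.

    ``exposures`` maps substance code to either an
    :class:`~ngra.model.ExposureEstimate` (from which ``statistic`` is
    taken) or a plain exposure value in ug/kg bw/day. Every assigned or
    excluded substance must have an exposure; missing ones abort with the
    offending codes listed.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")

    def exposure_of(code: str) -> float | None:
        est = exposures.get(code)
        if est is None:
            return None
        if isinstance(est, ExposureEstimate):
            return est.statistic(statistic)
        return float(est)

    missing = [
        a.substance_code
        for a in assignments
        if a.outcome in (TtcOutcome.ttc_assigned, TtcOutcome.excluded)
        and exposure_of(a.substance_code) is None
    ]
    if missing:
        raise ValueError(
            f"no exposure estimate for substance(s): {sorted(missing)}"
        )

    records: list[PriorityRecord] = []
    for assignment in assignments:
        exposure = exposure_of(assignment.substance_code)
        if assignment.outcome is TtcOutcome.no_structure:
            records.append(
                PriorityRecord(
                    substance_code=assignment.substance_code,
                    exposure_stat=exposure,
                    ttc=assignment,
                    hq=None,
                    list=PriorityList.unevaluated,
                )
            )
        elif assignment.outcome is TtcOutcome.excluded:
            member = exposure >= cutoff  # inclusive per the >= 0.5 rule
            records.append(
                PriorityRecord(
                    substance_code=assignment.substance_code,
                    exposure_stat=exposure,
                    ttc=assignment,
                    hq=None,
                    list=(
                        PriorityList.ttc_excluded_priority
                        if member
                        else PriorityList.not_priority
                    ),
                )
            )
        else:
            # exposure may legitimately be 0 (e.g. lower bound, all censored);
            # the quotient is then 0 and the substance is not a priority
            hq = (
                hazard_quotient(exposure, assignment.ttc_value)
                if exposure > 0
                else 0.0
            )
            records.append(
                PriorityRecord(
                    substance_code=assignment.substance_code,
                    exposure_stat=exposure,
                    ttc=assignment,
                    hq=hq,
                    # strict > 1: HQ exactly 1 is not a priority
                    list=(
                        PriorityList.ttc_priority
                        if hq > 1.0
                        else PriorityList.not_priority
                    ),
                )
            )
    return records


def select_for_screening(
    records: Sequence[PriorityRecord],
    per_class_counts: Mapping[float, int] | None = None,
) -> list[PriorityRecord]:
    """Pick the highest-HQ substances per TTC class for screening.

    Within each class, records sort by descending HQ, ties broken by
    descending exposure then ascending substance code; the top *k* per
    class are kept. The returned subset is ordered by TTC ascending then
    HQ descending (the presentation order of the screening table).
    """
    counts = dict(DEFAULT_CLASS_COUNTS if per_class_counts is None
                  else per_class_counts)
    if any(k < 0 for k in counts.values()):
        raise ValueError("per-class counts must be >= 0")

    eligible = [r for r in records if r.list is PriorityList.ttc_priority]
    for r in eligible:
        if r.hq is None:
            raise ValueError(f"record {r.substance_code} lacks an HQ")

    by_class: dict[float, list[PriorityRecord]] = {}
    for r in eligible:
        by_class.setdefault(r.ttc.ttc_value, []).append(r)

    selected: list[PriorityRecord] = []
    for ttc_value in sorted(by_class):
        members = sorted(
            by_class[ttc_value],
            key=lambda r: (-r.hq, -(r.exposure_stat or 0.0), r.substance_code),
        )
        k = counts.get(ttc_value, 0)
        selected.extend(members[:k])
    return selected
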