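"""Cross-assay normalization of heterogeneous HTS potency readouts.

The screening models report potency in incompatible ways — composite
(ToxPi-style) scores, percentage activity, 50% active concentrations
(AC50, uM), potency-list ranks, or lowest effect levels (LEL, uM). To
compare them, each readout is first mapped to an intermediate *potency*
that increases with toxicological potency:

* composite_score, percent — identity;
* ac50, lel — -log10(concentration in uM), so lower concentrations
  (more potent) score higher;
* rank — (N - rank + 1) over the N actives, so rank 1 scores highest.

Within each model's dataset the active potencies are then min-max scaled
to [0, 100] with the most potent substance anchored at exactly 100 (the
single stated anchor; the 0 anchor at the least potent active is this
module's documented choice). Inactive and untested substances carry no
score and are never conflated with one another.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from ngra.model import (
    HtsRawRecord,
    HtsScore,
    HtsStatus,
    PriorityRecord,
    ReadoutType,
)

#: Toxicological domains used to group models in the screening matrix:
#: endocrine perturbation, metabolic disorder, developmental toxicity,
#: cancer-related, hepatotoxicity.
DOMAINS = ("E", "M", "D", "C", "H")


def potency_transform(
    value: float, readout_type: ReadoutType, n_actives: int | None = None
) -> float:
    """Map one raw active readout onto the common potency scale.

    ``n_actives`` is required for rank readouts (the reversal needs the
    dataset size N): rank r becomes N - r + 1.
    """
    readout_type = ReadoutType(readout_type)
    if readout_type in (ReadoutType.composite_score, ReadoutType.percent):
        return float(value)
    if readout_type in (ReadoutType.ac50, ReadoutType.lel):
        if value <= 0:
            raise ValueError(
                f"{readout_type.value} must be a positive concentration, got {value}"
            )
        return -math.log10(value)
    # rank
    if n_actives is None:
        raise ValueError("rank transform requires the number of actives")
    if not (1 <= value <= n_actives):
        raise ValueError(f"rank {value} outside 1..{n_actives}")
    return float(n_actives - value + 1)


def normalize_dataset(potencies: Sequence[float]) -> list[float]:
    """Min-max scale one model's active potencies to [0, 100], max = 100.

    With a single active, or all potencies equal, every score is 100 (the
    most potent substance is always anchored at exactly 100).
    """
    if len(potencies) == 0:
        raise ValueError("cannot normalize an empty active set")
    p_min = min(potencies)
    p_max = max(potencies)
    if p_max == p_min:
        return [100.0] * len(potencies)
    span = p_max - p_min
    # anchor the extremes exactly; interior points clamp against rounding
    return [
        100.0 if p == p_max
        else 0.0 if p == p_min
        else min(100.0, max(0.0, 100.0 * ((p - p_min) / span)))
        for p in potencies
    ]


def score_model(records: Sequence[HtsRawRecord]) -> list[HtsScore]:
    """Normalize one prediction model's raw table into HtsScore records.

    All records must belong to a single model and share one readout type
    among the actives. Inactive / untested records pass through unscored.
    """
    model_ids = {r.model_id for r in records}
    if len(model_ids) > 1:
        raise ValueError(f"records span multiple models: {sorted(model_ids)}")
    actives = [r for r in records if r.status is HtsStatus.active]
    scores: list[HtsScore] = []
    if actives:
        readouts = {r.readout_type for r in actives}
        if len(readouts) > 1:
            raise ValueError(
                f"mixed readout types within one model: "
                f"{sorted(r.value for r in readouts)}"
            )
        readout = actives[0].readout_type
        n = len(actives)
        potencies = [potency_transform(r.value, readout, n_actives=n)
                     for r in actives]
        normalized = normalize_dataset(potencies)
        for rec, pot, norm in zip(actives, potencies, normalized):
            scores.append(
                HtsScore(
                    model_id=rec.model_id,
                    substance_code=rec.substance_code,
                    readout_type=rec.readout_type,
                    raw=rec.value,
                    potency=pot,
                    normalized=norm,
                    status=HtsStatus.active,
                )
            )
    for rec in records:
        if rec.status is not HtsStatus.active:
            scores.append(
                HtsScore(
                    model_id=rec.model_id,
                    substance_code=rec.substance_code,
                    readout_type=rec.readout_type,
                    raw=None,
                    potency=None,
                    normalized=None,
                    status=rec.status,
                )
            )
    return scores


def score_all(records: Sequence[HtsRawRecord]) -> list[HtsScore]:
    """Normalize every model's records, model by model."""
    by_model: dict[str, list[HtsRawRecord]] = {}
    for r in records:
        by_model.setdefault(r.model_id, []).append(r)
    out: list[HtsScore] = []
    for model_id in sorted(by_model):
        out.extend(score_model(by_model[model_id]))
    return out


def assemble_matrix(
    scores: Sequence[HtsScore],
    substances: Sequence[PriorityRecord] | Sequence[str],
    domain_map: Mapping[str, str],
) -> pd.DataFrame:
    """Build the substance x model screening matrix.

    Rows follow the given substance order; when
    :class:`~ngra.model.PriorityRecord` objects are supplied they are
    ordered by TTC ascending then HQ descending (the screening-table
    presentation order). Columns are models grouped by toxicological
    domain. Cells carry the normalized score, ``"not_active"`` or
    ``"not_tested"``; a substance absent from a model is ``"not_tested"``
    for that model, and substances absent from *every* model are flagged
    in the DataFrame attribute ``no_hts_data``.
    """
    models = sorted({s.model_id for s in scores})
    unknown = [m for m in models if m not in domain_map]
    if unknown:
        raise ValueError(f"model(s) missing from domain map: {unknown}")
    bad_domains = {m: d for m, d in domain_map.items() if d not in DOMAINS}
    if bad_domains:
        raise ValueError(
            f"unknown domain(s) {sorted(set(bad_domains.values()))}; "
            f"expected one of {DOMAINS}"
        )

    if substances and isinstance(substances[0], PriorityRecord):
        ordered = sorted(
            substances,
            key=lambda r: (
                r.ttc.ttc_value if r.ttc.ttc_value is not None else math.inf,
                -(r.hq if r.hq is not None else -math.inf),
                r.substance_code,
            ),
        )
        row_codes = [r.substance_code for r in ordered]
    else:
        row_codes = list(substances)

    columns = sorted(models, key=lambda m: (DOMAINS.index(domain_map[m]), m))
    cell: dict[tuple[str, str], object] = {}
    for s in scores:
        key = (s.substance_code, s.model_id)
        if s.status is HtsStatus.active:
            cell[key] = s.normalized
        else:
            cell[key] = s.status.value

    data = {
        model: [cell.get((code, model), HtsStatus.not_tested.value)
                for code in row_codes]
        for model in columns
    }
    matrix = pd.DataFrame(data, index=pd.Index(row_codes, name="substance_code"),
                          columns=columns)
    covered = {code for code, _ in cell}
    matrix.attrs["no_hts_data"] = tuple(c for c in row_codes if c not in covered)
    matrix.attrs["domains"] = {m: domain_map[m] for m in columns}
    return matrix
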