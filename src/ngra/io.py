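"""Readers and writers for the pipeline's five CSV dialects.

The dialects are this project's own documented flat schemas, modelled on
the coding conventions of EFSA's SSD1 sample description and FoodEx1
food classification but deliberately minimal: UTF-8, comma-separated,
"." decimal, one header row. Column sets are listed per reader below.

Readers validate every row into the typed records of :mod:`ngra.model`;
malformed rows are reported with their line numbers. Invalid SMILES do
not abort a load: the record is kept with no structure (and a warning
logged), because structure-less substances remain in the study as
"awaiting further prioritization".
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from ngra.model import (
    ALERT_FIELDS,
    AlertProfile,
    ConcentrationSample,
    ConsumptionRecord,
    CramerClass,
    ExclusionFlag,
    HtsRawRecord,
    HtsStatus,
    PriorityList,
    PriorityRecord,
    ReadoutType,
    ResultType,
    TranslationEntry,
    TtcOutcome,
)

logger = logging.getLogger("ngra")

# RDKit writes parse diagnostics to its own C++ logger; invalid SMILES are
# an expected, handled condition here.
RDLogger.DisableLog("rdApp.error")


class TableFormatError(ValueError):
    """Header or file-level problem: missing columns, duplicate keys."""


class TableValidationError(ValueError):
    """One or more rows violated a record invariant; message lists them."""


def parse_smiles(smiles: str) -> Optional[Chem.Mol]:
    """Parse a SMILES string, returning ``None`` if it is not a valid molecule."""
    if not smiles or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory column(s) {missing}")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _opt_float(raw: str) -> Optional[float]:
    return float(raw) if raw.strip() != "" else None


def _collect(rows_and_errors):
    records, errors = [], []
    for lineno, result in rows_and_errors:
        if isinstance(result, Exception):
            errors.append(f"line {lineno}: {result}")
        else:
            records.append(result)
    return records, errors


CONCENTRATION_COLUMNS = ("substance_code", "commodity_code", "result_type",
                         "value", "lod", "loq")


def read_concentration_table(path) -> list[ConcentrationSample]:
    """Read analytical concentration results (mg/kg commodity).

    Columns: substance_code, commodity_code, result_type (VAL | ND_LOD |
    ND_LOQ), value, lod, loq. Empty cells denote absent values.
    """
    df = _read_csv(path)
    _require_columns(df, CONCENTRATION_COLUMNS, path)

    def build(row):
        return ConcentrationSample(
            substance_code=row.substance_code,
            commodity_code=row.commodity_code,
            result_type=ResultType(row.result_type),
            value=_opt_float(row.value),
            lod=_opt_float(row.lod),
            loq=_opt_float(row.loq),
        )

    records, errors = _collect(
        (i + 2, _try(build, row)) for i, row in enumerate(df.itertuples(index=False))
    )
    if errors:
        raise TableValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return records


def _try(fn, *args):
    try:
        return fn(*args)
    except (ValueError, KeyError) as exc:
        return exc


CONSUMPTION_COLUMNS = ("subject_id", "day", "food_code", "amount",
                       "body_weight", "survey_weight")


def read_consumption_table(path) -> list[ConsumptionRecord]:
    """Read the individual consumption diary (amounts in g/day).

    Columns: subject_id, day, food_code, amount, body_weight, survey_weight.
    Subject-level fields (body weight, survey weight) must be constant
    within a subject.
    """
    df = _read_csv(path)
    _require_columns(df, CONSUMPTION_COLUMNS, path)

    def build(row):
        return ConsumptionRecord(
            subject_id=row.subject_id,
            day=int(row.day),
            food_code=row.food_code,
            amount=float(row.amount),
            body_weight=float(row.body_weight),
            survey_weight=float(row.survey_weight),
        )

    records, errors = _collect(
        (i + 2, _try(build, row)) for i, row in enumerate(df.itertuples(index=False))
    )
    if errors:
        raise TableValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    per_subject = {}
    for rec in records:
        key = (rec.body_weight, rec.survey_weight)
        prev = per_subject.setdefault(rec.subject_id, key)
        if prev != key:
            raise TableValidationError(
                f"{path}: subject {rec.subject_id} has inconsistent "
                f"body_weight/survey_weight across rows"
            )
    return records


TRANSLATION_COLUMNS = ("food_code", "commodity_code", "percent")


def read_translation_table(path) -> list[TranslationEntry]:
    """Read the food -> raw-commodity translation table (percent by mass)."""
    df = _read_csv(path)
    _require_columns(df, TRANSLATION_COLUMNS, path)

    def build(row):
        return TranslationEntry(
            food_code=row.food_code,
            commodity_code=row.commodity_code,
            percent=float(row.percent),
        )

    records, errors = _collect(
        (i + 2, _try(build, row)) for i, row in enumerate(df.itertuples(index=False))
    )
    if errors:
        raise TableValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    seen = set()
    for rec in records:
        key = (rec.food_code, rec.commodity_code)
        if key in seen:
            raise TableValidationError(f"{path}: duplicate translation entry {key}")
        seen.add(key)
    return records


ANNOTATION_COLUMNS = ("code", "name", "smiles", "exclusion_flags",
                      "cramer_class") + ALERT_FIELDS


def read_annotations(path):
    """Read substance annotations, validating SMILES at load time.

    Columns: code, name, smiles, exclusion_flags (semicolon-separated flag
    names, may be empty), cramer_class (I | II | III or empty), and the six
    alert booleans (true/false, all empty = no alert evaluation available).
    A syntactically invalid SMILES demotes the record to "no structure"
    with a logged warning; it does not abort the load.
    """
    from ngra.model import SubstanceAnnotation

    df = _read_csv(path)
    _require_columns(df, ANNOTATION_COLUMNS, path)

    def build(row):
        smiles = row.smiles.strip() or None
        if smiles is not None and parse_smiles(smiles) is None:
            logger.warning(
                "substance %s: invalid SMILES %r; keeping record without structure",
                row.code, smiles,
            )
            smiles = None
        flags = frozenset(
            ExclusionFlag(f.strip())
            for f in row.exclusion_flags.split(";")
            if f.strip()
        )
        alert_raw = [getattr(row, f).strip().lower() for f in ALERT_FIELDS]
        if all(v == "" for v in alert_raw):
            alerts = None
        else:
            bools = {}
            for field, v in zip(ALERT_FIELDS, alert_raw):
                if v not in ("true", "false"):
                    raise ValueError(
                        f"alert column {field} must be true/false (or all six "
                        f"empty), got {v!r}"
                    )
                bools[field] = v == "true"
            alerts = AlertProfile(**bools)
        cramer = CramerClass(row.cramer_class) if row.cramer_class.strip() else None
        return SubstanceAnnotation(
            code=row.code, name=row.name, smiles=smiles,
            exclusion_flags=flags, alerts=alerts, cramer_class=cramer,
        )

    records, errors = _collect(
        (i + 2, _try(build, row)) for i, row in enumerate(df.itertuples(index=False))
    )
    if errors:
        raise TableValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    codes = [r.code for r in records]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        raise TableFormatError(f"{path}: duplicate substance code(s) {sorted(dupes)}")
    return records


HTS_COLUMNS = ("model_id", "substance_code", "readout_type", "value", "status")


def read_hts_table(path) -> list[HtsRawRecord]:
    """Read one prediction model's raw HTS results.

    Columns: model_id, substance_code, readout_type (composite_score |
    percent | ac50 | rank | lel), value (empty unless active), status
    (active | not_active | not_tested). Concentrations are in uM.
    """
    df = _read_csv(path)
    _require_columns(df, HTS_COLUMNS, path)

    def build(row):
        return HtsRawRecord(
            model_id=row.model_id,
            substance_code=row.substance_code,
            readout_type=ReadoutType(row.readout_type),
            value=_opt_float(row.value),
            status=HtsStatus(row.status),
        )

    records, errors = _collect(
        (i + 2, _try(build, row)) for i, row in enumerate(df.itertuples(index=False))
    )
    if errors:
        raise TableValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    for model_id in {r.model_id for r in records}:
        ranks = [r.value for r in records
                 if r.model_id == model_id and r.status is HtsStatus.active
                 and r.readout_type is ReadoutType.rank]
        if len(ranks) != len(set(ranks)):
            raise TableValidationError(
                f"{path}: duplicate rank values within model {model_id}"
            )
    return records


# ---------------------------------------------------------------------------
# Writers (inverse of the readers; write-then-read round-trips exactly)
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    return "" if v is None else repr(float(v))


def write_concentration_table(samples: Iterable[ConcentrationSample], path) -> None:
    rows = [
        {
            "substance_code": s.substance_code,
            "commodity_code": s.commodity_code,
            "result_type": s.result_type.value,
            "value": _fmt(s.value),
            "lod": _fmt(s.lod),
            "loq": _fmt(s.loq),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(CONCENTRATION_COLUMNS)).to_csv(path, index=False)


def write_consumption_table(records: Iterable[ConsumptionRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "day": r.day,
            "food_code": r.food_code,
            "amount": _fmt(r.amount),
            "body_weight": _fmt(r.body_weight),
            "survey_weight": _fmt(r.survey_weight),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CONSUMPTION_COLUMNS)).to_csv(path, index=False)


def write_translation_table(entries: Iterable[TranslationEntry], path) -> None:
    rows = [
        {
            "food_code": e.food_code,
            "commodity_code": e.commodity_code,
            "percent": _fmt(e.percent),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=list(TRANSLATION_COLUMNS)).to_csv(path, index=False)


def write_annotations(annotations, path) -> None:
    rows = []
    for a in annotations:
        row = {
            "code": a.code,
            "name": a.name,
            "smiles": a.smiles or "",
            "exclusion_flags": ";".join(sorted(f.value for f in a.exclusion_flags)),
            "cramer_class": a.cramer_class.value if a.cramer_class else "",
        }
        for field in ALERT_FIELDS:
            row[field] = (
                "" if a.alerts is None
                else str(getattr(a.alerts, field)).lower()
            )
        rows.append(row)
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


def write_hts_table(records: Iterable[HtsRawRecord], path) -> None:
    rows = [
        {
            "model_id": r.model_id,
            "substance_code": r.substance_code,
            "readout_type": r.readout_type.value,
            "value": _fmt(r.value),
            "status": r.status.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(HTS_COLUMNS)).to_csv(path, index=False)


PRIORITY_COLUMNS = ("substance_code", "exposure_stat", "ttc_outcome", "ttc_value",
                    "hq", "list", "decision_path", "exclusion_reason")


def write_priority_report(records: Sequence[PriorityRecord], out_dir,
                          metadata: Optional[dict] = None) -> dict[str, Path]:
    """Write the three priority lists plus a run-metadata JSON.

    Emits ``ttc_applicable_priorities.csv`` (TTC assigned, HQ > 1),
    ``ttc_excluded_priorities.csv`` (TTC-excluded, exposure over the
    cutoff) and ``unevaluated.csv`` (no structure), plus ``report_meta.json``
    with the list counts and any caller-supplied metadata (seed, config
    hash). Records routed to ``ttc_applicable_priorities`` must carry an HQ.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    by_list = {
        PriorityList.ttc_priority: [],
        PriorityList.ttc_excluded_priority: [],
        PriorityList.unevaluated: [],
    }
    for rec in records:
        if rec.list in by_list:
            if rec.list is PriorityList.ttc_priority and rec.hq is None:
                raise ValueError(
                    f"record {rec.substance_code} in ttc_priority list lacks an HQ"
                )
            by_list[rec.list].append(rec)

    def to_row(rec: PriorityRecord) -> dict:
        return {
            "substance_code": rec.substance_code,
            "exposure_stat": _fmt(rec.exposure_stat),
            "ttc_outcome": rec.ttc.outcome.value,
            "ttc_value": _fmt(rec.ttc.ttc_value),
            "hq": _fmt(rec.hq),
            "list": rec.list.value,
            "decision_path": ";".join(rec.ttc.decision_path),
            "exclusion_reason": rec.ttc.exclusion_reason or "",
        }

    names = {
        PriorityList.ttc_priority: "ttc_applicable_priorities.csv",
        PriorityList.ttc_excluded_priority: "ttc_excluded_priorities.csv",
        PriorityList.unevaluated: "unevaluated.csv",
    }
    written = {}
    for lst, fname in names.items():
        fpath = out_dir / fname
        pd.DataFrame([to_row(r) for r in by_list[lst]],
                     columns=list(PRIORITY_COLUMNS)).to_csv(fpath, index=False)
        written[fname] = fpath

    meta = dict(metadata or {})
    meta["counts"] = {names[lst]: len(recs) for lst, recs in by_list.items()}
    meta["n_records"] = len(records)
    meta_path = out_dir / "report_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written["report_meta.json"] = meta_path
    return written
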