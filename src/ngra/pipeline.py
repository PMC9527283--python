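"""End-to-end orchestration: simulate -> exposure -> TTC -> prioritize -> HTS.

A run is driven by a single :class:`RunConfig` (loadable from YAML with
CLI overrides) and produces a self-contained run directory::

    run_dir/
      inputs/        the five input tables (written here when simulated)
      intermediate/  exposure summaries and TTC assignments
      reports/       priority lists, screening selection, HTS matrix,
                     funnel counts, resolved config (+ content hash)
      logs/          stage-level log with per-stage record counts

Record conservation is a first-class artifact: the funnel report counts
substances entering each stage and every side list (excluded,
unevaluated, below-threshold), and the counts always reconcile — no
record is silently dropped. Two runs with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ngra import io as ngio
from ngra.exposure import Scenario, compute_exposures, exposures_to_frame
from ngra.hts import assemble_matrix, score_all
from ngra.model import PriorityList, TtcOutcome
from ngra.prioritize import (
    DEFAULT_CLASS_COUNTS,
    DEFAULT_EXCLUDED_CUTOFF,
    build_lists,
    select_for_screening,
)
from ngra.synth import SyntheticScenario, generate_scenario
from ngra.ttc import SubstructureMode, assign_ttc

logger = logging.getLogger("ngra")


class StageError(RuntimeError):
    """An error attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    #: censoring scenario used for prioritization ("both" also writes the
    #: lower-bound table; the upper bound is preferred for decisions)
    scenario: str = "upper"
    exposure_statistic: str = "mean"   # mean | median | p95
    substructure_mode: SubstructureMode = SubstructureMode.literal
    cutoff: float = DEFAULT_EXCLUDED_CUTOFF       # ug/kg bw/day, inclusive
    per_class_counts: dict[float, int] = Field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    seed: int = 0
    #: paths to the five input tables; leave None to simulate them
    concentrations: Optional[str] = None
    consumption: Optional[str] = None
    translation: Optional[str] = None
    annotations: Optional[str] = None
    hts_tables: tuple[str, ...] = ()
    #: model_id -> domain letter (E/M/D/C/H) for the screening matrix
    domain_map: dict[str, str] = Field(default_factory=dict)
    synthetic: Optional[SyntheticScenario] = None

    @model_validator(mode="after")
    def _valid(self) -> "RunConfig":
        if self.scenario not in ("lower", "upper", "both"):
            raise ValueError("scenario must be lower, upper or both")
        if self.exposure_statistic not in ("mean", "median", "p95"):
            raise ValueError("exposure_statistic must be mean, median or p95")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if any(v < 0 for v in self.per_class_counts.values()):
            raise ValueError("per-class counts must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_run_logger(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    return handler


def run(config: RunConfig, run_dir) -> Path:
    """Execute the full pipeline; returns the run directory path.

    Any stage failure aborts with a :class:`StageError` naming the stage.
    """
    run_dir = Path(run_dir)
    for sub in ("inputs", "intermediate", "reports", "logs"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(run_dir / "logs" / "run.log")
    try:
        return _run_stages(config, run_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, run_dir: Path) -> Path:
    inputs_dir = run_dir / "inputs"
    inter_dir = run_dir / "intermediate"
    reports_dir = run_dir / "reports"

    # ---- stage: inputs ----------------------------------------------------
    try:
        if config.synthetic is not None or config.concentrations is None:
            params = config.synthetic or SyntheticScenario(seed=config.seed)
            bundle = generate_scenario(params, seed=config.seed)
            bundle.write(inputs_dir)
            concentrations = bundle.concentrations
            consumption = bundle.consumption
            translation = bundle.translation
            annotations = bundle.annotations
            hts_records = [r for recs in bundle.hts_tables.values() for r in recs]
            domain_map = config.domain_map or _default_domain_map(
                bundle.hts_tables.keys()
            )
            logger.info("inputs: simulated scenario (seed=%d)", config.seed)
        else:
            concentrations = ngio.read_concentration_table(config.concentrations)
            consumption = ngio.read_consumption_table(config.consumption)
            translation = ngio.read_translation_table(config.translation)
            annotations = ngio.read_annotations(config.annotations)
            hts_records = []
            for path in config.hts_tables:
                hts_records.extend(ngio.read_hts_table(path))
            domain_map = config.domain_map
            logger.info("inputs: loaded from configured paths")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", str(exc)) from exc
    logger.info(
        "inputs: %d concentration samples, %d consumption records, "
        "%d translation entries, %d substances, %d HTS records",
        len(concentrations), len(consumption), len(translation),
        len(annotations), len(hts_records),
    )

    # ---- stage: exposure --------------------------------------------------
    codes = [a.code for a in annotations]
    scenarios = {
        "lower": [Scenario.lower_bound],
        "upper": [Scenario.upper_bound],
        "both": [Scenario.lower_bound, Scenario.upper_bound],
    }[config.scenario]
    decision_scenario = (
        Scenario.upper_bound if config.scenario in ("upper", "both")
        else Scenario.lower_bound
    )
    try:
        exposures_by_scenario = {}
        for scen in scenarios:
            exposures_by_scenario[scen] = compute_exposures(
                concentrations, consumption, translation, scen, substances=codes
            )
            frame = exposures_to_frame(exposures_by_scenario[scen])
            frame.to_csv(inter_dir / f"exposure_{scen.value}.csv", index=False)
    except Exception as exc:
        raise StageError("exposure", str(exc)) from exc
    exposures = exposures_by_scenario[decision_scenario]
    logger.info(
        "exposure: %d substances summarized (%s, statistic=%s)",
        len(exposures), decision_scenario.value, config.exposure_statistic,
    )

    # ---- stage: ttc -------------------------------------------------------
    try:
        assignments = [
            assign_ttc(a, config.substructure_mode) for a in annotations
        ]
    except Exception as exc:
        raise StageError("ttc", str(exc)) from exc
    ttc_frame = [
        {
            "substance_code": t.substance_code,
            "outcome": t.outcome.value,
            "ttc_value": "" if t.ttc_value is None else t.ttc_value,
            "decision_path": ";".join(t.decision_path),
            "exclusion_reason": t.exclusion_reason or "",
        }
        for t in assignments
    ]
    import pandas as pd

    pd.DataFrame(ttc_frame).to_csv(inter_dir / "ttc_assignments.csv", index=False)
    n_excluded = sum(t.outcome is TtcOutcome.excluded for t in assignments)
    n_assigned = sum(t.outcome is TtcOutcome.ttc_assigned for t in assignments)
    n_nostruct = sum(t.outcome is TtcOutcome.no_structure for t in assignments)
    logger.info(
        "ttc: %d excluded, %d assigned, %d without structure",
        n_excluded, n_assigned, n_nostruct,
    )

    # ---- stage: prioritize ------------------------------------------------
    try:
        records = build_lists(
            exposures, assignments, cutoff=config.cutoff,
            statistic=config.exposure_statistic,
        )
        selection = select_for_screening(records, config.per_class_counts)
    except Exception as exc:
        raise StageError("prioritize", str(exc)) from exc
    counts = {lst: sum(r.list is lst for r in records) for lst in PriorityList}
    logger.info(
        "prioritize: %d ttc_priority, %d ttc_excluded_priority, "
        "%d unevaluated, %d not_priority; %d selected for screening",
        counts[PriorityList.ttc_priority],
        counts[PriorityList.ttc_excluded_priority],
        counts[PriorityList.unevaluated],
        counts[PriorityList.not_priority],
        len(selection),
    )

    # ---- stage: hts -------------------------------------------------------
    try:
        scores = score_all(hts_records)
        screened = selection + [
            r for r in records if r.list is PriorityList.ttc_excluded_priority
        ]
        if screened and domain_map:
            matrix = assemble_matrix(scores, screened, domain_map)
            matrix.to_csv(reports_dir / "hts_matrix.csv")
        else:
            matrix = None
    except Exception as exc:
        raise StageError("hts", str(exc)) from exc
    if matrix is not None:
        logger.info(
            "hts: matrix %d substances x %d models (%d with no HTS data)",
            matrix.shape[0], matrix.shape[1], len(matrix.attrs["no_hts_data"]),
        )

    # ---- reports ----------------------------------------------------------
    funnel = {
        "substances_in": len(annotations),
        "with_structure": sum(a.smiles is not None for a in annotations),
        "ttc_excluded": n_excluded,
        "ttc_assigned": n_assigned,
        "no_structure": n_nostruct,
        "hq_gt_1": counts[PriorityList.ttc_priority],
        "excluded_over_cutoff": counts[PriorityList.ttc_excluded_priority],
        "not_priority": counts[PriorityList.not_priority],
        "selected_for_screening": len(selection),
    }
    # conservation: the three outcomes partition the input set, and the four
    # lists partition it again
    assert (funnel["ttc_excluded"] + funnel["ttc_assigned"]
            + funnel["no_structure"]) == funnel["substances_in"]
    assert (funnel["hq_gt_1"] + funnel["excluded_over_cutoff"]
            + funnel["not_priority"] + funnel["no_structure"]) \
        == funnel["substances_in"]
    (reports_dir / "funnel.json").write_text(
        json.dumps(funnel, indent=2, sort_keys=True) + "\n"
    )

    resolved = config.model_dump(mode="json")
    resolved["config_hash"] = config.content_hash()
    (reports_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True)
    )

    ngio.write_priority_report(
        records, reports_dir,
        metadata={"seed": config.seed, "config_hash": config.content_hash()},
    )
    selection_rows = [
        {
            "substance_code": r.substance_code,
            "ttc_value": r.ttc.ttc_value,
            "hq": r.hq,
            "exposure_stat": r.exposure_stat,
        }
        for r in selection
    ]
    pd.DataFrame(
        selection_rows,
        columns=["substance_code", "ttc_value", "hq", "exposure_stat"],
    ).to_csv(reports_dir / "screening_selection.csv", index=False)

    logger.info("run complete")
    return run_dir


def _default_domain_map(model_ids) -> dict[str, str]:
    """Round-robin domain assignment for simulated models."""
    from ngra.hts import DOMAINS

    return {m: DOMAINS[i % len(DOMAINS)] for i, m in enumerate(sorted(model_ids))}
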