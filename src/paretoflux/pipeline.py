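"""The four-step knockout-design workflow as a reproducible pipeline.

1. Reference FBA — maximize biomass on the wild-type model.
2. Candidate identification — reactions carrying flux in the reference,
   minus the essential set (or all inessential reactions, configurable).
3. Bi-objective solve — the Pareto frontier of (target, biomass) under K
   deletions.
4. Per-point enumeration — every equivalent deletion set (mode "all") or
   only the MOMA distance-minimal ones (mode "moma").

Artifacts are written to ``output_dir`` with canonical sorting so identical
configurations reproduce identical bytes; a MANIFEST records content digests
and whether the run completed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pfio
from .enumeration import enumerate_equivalent, enumerate_moma
from .lp import SolverConfig, knockout_candidates, solve_fba
from .model import (
    apply_bound_overrides,
    cap_infinite_bounds,
    load_model,
    read_bound_overrides,
)
from .pareto import solve_bop

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    model_path: str
    output_dir: str
    dialect: str = "json"
    overrides_path: str | None = None
    bound_cap: float = 1000.0
    K: int = 1
    objectives: tuple[str, ...] = ()  # (target, ...); biomass is always appended
    biomass_id: str | None = None
    range_limits: dict = field(default_factory=dict)
    enumeration_mode: str = "all"  # "all" | "moma"
    max_sets: int = 1000
    candidate_mode: str = "nonzero_reference"  # | "all_inessential"
    cardinality_equality: bool = True
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be nonnegative")
        if self.enumeration_mode not in ("all", "moma"):
            raise ValueError("enumeration_mode must be 'all' or 'moma'")
        if self.candidate_mode not in ("nonzero_reference", "all_inessential"):
            raise ValueError(
                "candidate_mode must be 'nonzero_reference' or 'all_inessential'"
            )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, artifacts: list[str], complete: bool) -> None:
    manifest = {
        "complete": complete,
        "artifacts": {
            name: _digest(outdir / name) for name in sorted(artifacts) if (outdir / name).exists()
        },
    }
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _config_echo(config: PipelineConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["objectives"] = list(config.objectives)
    return doc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the four-step workflow; returns a summary dict.

    Writes ``reference_flux.tsv``, ``candidates.txt``, ``pareto_front.tsv``
    (+ ``.json``), ``enumeration.tsv``, ``run_log.json`` and
    ``MANIFEST.json`` under ``config.output_dir``. Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written so far are
    retained and the MANIFEST marks the run incomplete.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    log: dict = {"config": _config_echo(config), "stages": {}}
    stage = "load_model"
    try:
        model = load_model(
            config.model_path,
            dialect=config.dialect,
            biomass_id=config.biomass_id,
            target_ids=tuple(config.objectives),
        )
        if config.overrides_path:
            model = apply_bound_overrides(model, read_bound_overrides(config.overrides_path))
        model = cap_infinite_bounds(model, config.bound_cap)
        log["stages"][stage] = {
            "n_reactions": model.n_reactions,
            "n_metabolites": model.n_metabolites,
            "model_digest": model.digest(),
        }

        stage = "reference_fba"
        reference = solve_fba(model, config=config.solver)
        pfio.write_flux_tsv(reference, outdir / "reference_flux.tsv")
        artifacts.append("reference_flux.tsv")
        log["stages"][stage] = {"biomass_optimum": reference.objective_value}
        logger.info("step 1: reference FBA biomass optimum %.6g", reference.objective_value)

        stage = "candidates"
        if config.candidate_mode == "nonzero_reference":
            candidates = knockout_candidates(model, reference, config.solver)
        else:
            candidates = set(model.inessential_ids())
        order = {rid: i for i, rid in enumerate(model.reaction_ids)}
        candidate_list = sorted(candidates, key=order.__getitem__)
        with open(outdir / "candidates.txt", "w") as fh:
            for rid in candidate_list:
                fh.write(rid + "\n")
        artifacts.append("candidates.txt")
        log["stages"][stage] = {"n_candidates": len(candidate_list)}
        logger.info("step 2: %d knockout candidates", len(candidate_list))

        stage = "pareto_front"
        objective_ids = None
        if config.objectives:
            objective_ids = list(config.objectives) + [model.biomass_id]
        range_limits = {
            rid: tuple(v) for rid, v in (config.range_limits or {}).items()
        } or None
        front = solve_bop(
            model,
            config.K,
            range_limits=range_limits,
            config=config.solver,
            candidates=candidate_list,
            objective_ids=objective_ids,
            cardinality_equality=config.cardinality_equality,
        )
        obj_names = tuple(front.problem_spec["objective_ids"])
        pfio.write_front_tsv(front, outdir / "pareto_front.tsv", objective_names=obj_names)
        pfio.write_front_json(front, outdir / "pareto_front.json")
        artifacts += ["pareto_front.tsv", "pareto_front.json"]
        log["stages"][stage] = {"status": front.status, "n_points": len(front)}
        logger.info("step 3: frontier with %d points (status %s)", len(front), front.status)
        if front.status != "ok":
            raise PipelineError(f"stage {stage}: frontier solve returned {front.status}")

        stage = "enumeration"
        results = []
        for point in front.points:
            if config.enumeration_mode == "moma":
                res = enumerate_moma(
                    model, point, config.K,
                    reference=reference, config=config.solver,
                    max_sets=config.max_sets, candidates=candidate_list,
                    objective_ids=objective_ids,
                    cardinality_equality=config.cardinality_equality,
                )
            else:
                res = enumerate_equivalent(
                    model, point, config.K,
                    config=config.solver, max_sets=config.max_sets,
                    candidates=candidate_list, objective_ids=objective_ids,
                    cardinality_equality=config.cardinality_equality,
                )
            results.append(res)
        pfio.write_enumeration_tsv(results, outdir / "enumeration.tsv")
        artifacts.append("enumeration.tsv")
        n_sets = sum(len(r.knockout_sets) for r in results)
        log["stages"][stage] = {
            "mode": config.enumeration_mode,
            "n_sets_total": n_sets,
            "per_point": [
                {
                    "objectives": list(r.point.objectives),
                    "n_sets": len(r.knockout_sets),
                    "exhausted": r.exhausted,
                    "f_star": r.f_star,
                }
                for r in results
            ],
        }
        logger.info("step 4: %d equivalent deletion sets over %d points", n_sets, len(results))
    except PipelineError:
        _finish_log(outdir, log, artifacts, complete=False)
        raise
    except Exception as exc:
        _finish_log(outdir, log, artifacts, complete=False)
        raise PipelineError(f"stage {stage}: {exc}") from exc
    _finish_log(outdir, log, artifacts, complete=True)
    return log


def _finish_log(outdir: Path, log: dict, artifacts: list[str], complete: bool) -> None:
    log["complete"] = complete
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    _write_manifest(outdir, artifacts + ["run_log.json"], complete)
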