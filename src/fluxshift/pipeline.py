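"""Config-driven orchestration of the knock-out/over-expression analysis.

One run executes: load model → wild-type FBA (minimum-norm optimum) →
build KO and OE models → MOMA against the wild type for both arms →
classify each reaction's KO/OE response (10% rule) → summarize per
subsystem → write a report bundle:

* ``reactions.tsv`` — per-reaction fluxes, direction labels and verdict,
  plus one ``unidentified`` row per perturbation target missing from the
  model;
* ``subsystems.tsv`` — per-subsystem counts and fractions of
  flux-increasing/-decreasing reactions;
* ``run_metadata.json`` — model content hash, objective, preset, solver
  tolerances, missing reactions, solver statuses and stage wall times —
  enough to re-run the analysis exactly.

The core path is deterministic: identical configs produce byte-identical
TSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .exceptions import ConfigurationError, PipelineError
from .fluxdiff import (
    DEFAULT_ABS_FLOOR,
    DEFAULT_REL_THRESHOLD,
    KoOeClassification,
    SubsystemSummary,
    classifications_to_tsv,
    classify_ko_oe,
    summaries_to_tsv,
    summarize_subsystems,
)
from .metnet import MetabolicModel, load_model
from .perturb import (
    KEEP,
    BoundOverride,
    PerturbationSpec,
    apply_perturbation,
    hmgcs2_presets,
)
from .solvers import (
    DEFAULT_TOLERANCES,
    FluxDistribution,
    SolverTolerances,
    solve_fba,
    solve_moma,
)

log = logging.getLogger(__name__)

PRESET_NAMES = ("colon", "liver", "toy-ketone")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one perturbation-analysis run.

    ``perturbation`` is a preset name ("colon", "liver", "toy-ketone") or
    ``file:<path>`` pointing at a JSON document ``{"ko": <spec>, "oe":
    <spec>}``. ``ko_bound_override`` substitutes the colon knock-out
    lower bound of 9 (see :mod:`fluxshift.perturb`). ``seed`` is carried
    for stochastic sub-steps; the core path has none.
    """

    model_path: str
    perturbation: str
    output_dir: str
    model_format: str | None = None  # inferred from suffix when None
    rel_threshold: float = DEFAULT_REL_THRESHOLD
    abs_floor: float = DEFAULT_ABS_FLOOR
    ko_bound_override: float | None = None
    seed: int | None = None
    tolerances: SolverTolerances = field(default=DEFAULT_TOLERANCES)

    def __post_init__(self):
        if not self.rel_threshold > 0:
            raise ConfigurationError(
                f"rel_threshold must be > 0, got {self.rel_threshold}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        tol = doc.pop("tolerances", None)
        tolerances = SolverTolerances(**tol) if tol else DEFAULT_TOLERANCES
        return cls(tolerances=tolerances, **doc)

    def to_dict(self) -> dict:
        return {
            "model_path": self.model_path,
            "model_format": self.model_format,
            "perturbation": self.perturbation,
            "output_dir": self.output_dir,
            "rel_threshold": self.rel_threshold,
            "abs_floor": self.abs_floor,
            "ko_bound_override": self.ko_bound_override,
            "seed": self.seed,
            "tolerances": {
                "mass_balance": self.tolerances.mass_balance,
                "bound": self.tolerances.bound,
                "qp_convergence": self.tolerances.qp_convergence,
            },
        }


@dataclass(frozen=True)
class RunResult:
    """In-memory report bundle of one run."""

    config: RunConfig
    model: MetabolicModel
    wild_type: FluxDistribution
    ko_flux: FluxDistribution
    oe_flux: FluxDistribution
    ko_spec: PerturbationSpec
    oe_spec: PerturbationSpec
    missing: list[str]
    classifications: list[KoOeClassification]
    subsystem_summaries: list[SubsystemSummary]
    metadata: dict


def _resolve_specs(
    config: RunConfig, wild_type: FluxDistribution
) -> tuple[PerturbationSpec, PerturbationSpec]:
    name = config.perturbation
    if name in ("colon", "liver"):
        return hmgcs2_presets(name, ko_bound_override=config.ko_bound_override)
    if name == "toy-ketone":
        # strict KO of the HMGCS2 analog; OE forces 1.5× its wild-type flux
        wt_flux = wild_type.get("HMGCS2x", 0.0)
        ko = PerturbationSpec(
            name="toy-ketone-ko",
            mode="knockout",
            overrides=(BoundOverride("HMGCS2x", 0.0, 0.0),),
        )
        oe = PerturbationSpec(
            name="toy-ketone-oe",
            mode="overexpression",
            overrides=(BoundOverride("HMGCS2x", 1.5 * wt_flux, KEEP),),
        )
        return ko, oe
    if name.startswith("file:"):
        doc = json.loads(Path(name[len("file:") :]).read_text())
        return (
            PerturbationSpec.from_dict(doc["ko"]),
            PerturbationSpec.from_dict(doc["oe"]),
        )
    raise ConfigurationError(
        f"unknown perturbation {name!r}; expected one of {PRESET_NAMES} "
        "or file:<path>"
    )


def run_perturbation_analysis(config: RunConfig) -> RunResult:
    """Execute the full analysis described in the module docstring.

    Raises PipelineError when the model cannot be loaded or the wild-type
    FBA is not optimal; an infeasible perturbed arm is reported in the
    metadata and every reaction is classified ``unidentified``.
    """
    stages: dict[str, float] = {}
    t0 = time.perf_counter()
    model_path = Path(config.model_path)
    if not model_path.exists():
        raise PipelineError(f"model file not found: {model_path}")
    model = load_model(model_path, config.model_format)
    stages["load"] = time.perf_counter() - t0
    log.info("loaded model %s (%d reactions) in %.3fs",
             model.id, len(model.reactions), stages["load"])

    t = time.perf_counter()
    wild_type = solve_fba(model, config.tolerances)
    stages["fba_wild_type"] = time.perf_counter() - t
    log.info("wild-type FBA: status=%s objective=%s", wild_type.status,
             wild_type.objective_value)
    if wild_type.status != "optimal":
        raise PipelineError(
            f"wild-type FBA is {wild_type.status}; cannot take a reference flux"
        )

    ko_spec, oe_spec = _resolve_specs(config, wild_type)
    ko_model, ko_missing = apply_perturbation(model, ko_spec)
    oe_model, oe_missing = apply_perturbation(model, oe_spec)
    missing = list(dict.fromkeys(ko_missing + oe_missing))
    if missing:
        log.warning("perturbation targets missing from model: %s", missing)

    t = time.perf_counter()
    ko_flux = solve_moma(ko_model, wild_type, config.tolerances)
    stages["moma_ko"] = time.perf_counter() - t
    log.info("KO MOMA: status=%s distance²=%s", ko_flux.status,
             ko_flux.objective_value)
    t = time.perf_counter()
    oe_flux = solve_moma(oe_model, wild_type, config.tolerances)
    stages["moma_oe"] = time.perf_counter() - t
    log.info("OE MOMA: status=%s distance²=%s", oe_flux.status,
             oe_flux.objective_value)

    if ko_flux.status == "optimal" and oe_flux.status == "optimal":
        classifications = classify_ko_oe(
            wild_type,
            ko_flux,
            oe_flux,
            rel_threshold=config.rel_threshold,
            abs_floor=config.abs_floor,
            missing=missing,
        )
    else:
        # an arm failed: no comparison is meaningful for any reaction
        classifications = classify_ko_oe(
            wild_type, wild_type, wild_type,
            rel_threshold=config.rel_threshold,
            abs_floor=config.abs_floor,
            missing=list(wild_type.fluxes) + missing,
        )
        classifications = [c for c in classifications if c.verdict == "unidentified"]
    summaries = summarize_subsystems(
        [c for c in classifications if c.verdict != "unidentified"], model
    )

    metadata = {
        "fluxshift_version": __version__,
        "config": config.to_dict(),
        "model_id": model.id,
        "model_content_hash": model.content_hash(),
        "objective": dict(model.objective),
        "ko_spec": ko_spec.to_dict(),
        "oe_spec": oe_spec.to_dict(),
        "missing_reactions": missing,
        "solver_status": {
            "wild_type": wild_type.status,
            "ko": ko_flux.status,
            "oe": oe_flux.status,
        },
        "objective_values": {
            "wild_type_fba": wild_type.objective_value,
            "ko_moma_distance_sq": ko_flux.objective_value,
            "oe_moma_distance_sq": oe_flux.objective_value,
        },
    }
    # stage wall times go to the log only, keeping the report bundle
    # byte-identical across reruns of the same config
    log.info("stage seconds: %s", {k: round(v, 3) for k, v in stages.items()})

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    classifications_to_tsv(classifications, model, out / "reactions.tsv")
    summaries_to_tsv(summaries, out / "subsystems.tsv")
    (out / "run_metadata.json").write_text(
        json.dumps(metadata, indent=1, sort_keys=True) + "\n"
    )

    return RunResult(
        config=config,
        model=model,
        wild_type=wild_type,
        ko_flux=ko_flux,
        oe_flux=oe_flux,
        ko_spec=ko_spec,
        oe_spec=oe_spec,
        missing=missing,
        classifications=classifications,
        subsystem_summaries=summaries,
        metadata=metadata,
    )
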