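"""End-to-end orchestration: model → FBA → threshold → GIMME → activity →
reporter, from a single configuration, with a machine-readable manifest.

The manifest records every parameter plus the per-condition threshold,
FBA maximum, inconsistency score and active-reaction count — the numbers
needed to debug a divergence between two runs — and is re-executable:
identical inputs and seed reproduce all numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from tigsmm.activity import compare_conditions
from tigsmm.expression import (
    ThresholdConfig,
    compute_threshold,
    map_expression,
    read_fpkm,
)
from tigsmm.fba import UptakeConstraint, apply_uptake, solve_fba
from tigsmm.gimme import (
    GimmeConfig,
    compute_penalties,
    context_reaction_states,
    solve_gimme,
)
from tigsmm.model_io import census, read_model
from tigsmm.reporter import (
    build_neighborhoods,
    read_gene_stats,
    reporter_scores,
    significant_reporters,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "PipelineError"]

logger = logging.getLogger("tigsmm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one replication run needs.

    ``carbon`` maps each condition name to its (exchange reaction id,
    uptake rate) pair; ``gene_stats`` maps condition to a gene-statistics
    TSV (or names a single file shared by all conditions) and may be
    omitted to skip the reporter stage.
    """

    model_path: str
    fpkm_path: str
    output_dir: str
    conditions: List[str]
    carbon: Dict[str, Tuple[str, float]]
    open_nutrients: List[str] = field(default_factory=list)
    gene_stats: Optional[Union[str, Dict[str, str]]] = None
    percentile: float = 50.0
    threshold_population: str = "metabolic_genes"
    mapping_rule: str = "max_over_genes"
    growth_fraction: float = 0.90
    zero_tolerance: float = 1e-6
    alpha: float = 0.05
    n_samples: int = 10_000
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["carbon"] = {k: tuple(v) for k, v in raw["carbon"].items()}
        return RunConfig(**raw)

    def validate(self) -> None:
        for cond in self.conditions:
            if cond not in self.carbon:
                raise ValueError(f"condition {cond!r} has no carbon entry")
        for p in (self.model_path, self.fpkm_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunManifest:
    """Record of one run; JSON-serializable."""

    config: dict
    model_census: dict
    per_condition: Dict[str, dict]
    venn: Optional[dict]
    reporters: Dict[str, dict]
    version: str
    started: float
    finished: float
    failed_stage: Optional[str] = None

    def to_json(self, path) -> Path:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return Path(path)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and write outputs under
    ``config.output_dir``.

    Per condition: medium setup, threshold, expression mapping, GIMME and
    active-state calls (flux and penalty TSVs written per condition).
    Across the first two conditions: the Venn partition of active sets.
    If gene statistics are configured: reporter scores and significant
    calls per condition.  A failure in any stage aborts with the stage
    name; the manifest written so far carries a FAILED marker.
    """
    from tigsmm import __version__

    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()

    model = _stage("model_io")(read_model)(config.model_path)
    model_census = census(model).as_dict()
    logger.info("model %s: %s", model.id, model_census)

    profiles = _stage("expression")(read_fpkm)(config.fpkm_path)
    by_condition = {p.condition: p for p in profiles}

    per_condition: Dict[str, dict] = {}
    active_sets: Dict[str, set] = {}
    reporters: Dict[str, dict] = {}
    failed: Optional[str] = None
    venn = None

    try:
        for cond in config.conditions:
            if cond not in by_condition:
                raise PipelineError(
                    "expression", KeyError(f"condition {cond!r} not in FPKM table")
                )
            profile = by_condition[cond]
            ex_id, rate = config.carbon[cond]
            medium = _stage("fba")(apply_uptake)(
                model, [UptakeConstraint(ex_id, rate)], config.open_nutrients
            )
            tcfg = ThresholdConfig(
                percentile=config.percentile, population=config.threshold_population
            )
            threshold = _stage("expression")(compute_threshold)(profile, model, tcfg)
            rxn_expr = _stage("expression")(map_expression)(
                model, profile, config.mapping_rule
            )
            penalties = _stage("gimme")(compute_penalties)(rxn_expr, threshold)
            gcfg = GimmeConfig(
                growth_fraction=config.growth_fraction,
                zero_tolerance=config.zero_tolerance,
                threshold_config=tcfg,
            )
            solution = _stage("gimme")(solve_gimme)(medium, penalties, gcfg)
            if solution.status != "optimal":
                raise PipelineError(
                    "gimme", RuntimeError(f"{cond}: GIMME status {solution.status}")
                )
            states = context_reaction_states(solution, config.zero_tolerance)
            active = {r for r, s in states.items() if s == "active"}
            active_sets[cond] = active

            flux_path = out_dir / f"fluxes_{cond}.tsv"
            pd.DataFrame(
                {"reaction_id": list(solution.fluxes),
                 "flux": list(solution.fluxes.values())}
            ).to_csv(flux_path, sep="\t", index=False)
            pen_path = out_dir / f"penalties_{cond}.tsv"
            pd.DataFrame(
                {"reaction_id": list(penalties.values),
                 "c_i": list(penalties.values.values())}
            ).to_csv(pen_path, sep="\t", index=False)

            per_condition[cond] = {
                "carbon_exchange": ex_id,
                "uptake_rate": rate,
                "x_threshold": threshold,
                "fba_maximum": solution.fba_maximum,
                "growth_rate": solution.growth_rate,
                "inconsistency_score": solution.inconsistency_score,
                "n_active": len(active),
            }
            logger.info("condition %s: %s", cond, per_condition[cond])

        if len(config.conditions) >= 2:
            a, b = config.conditions[:2]
            venn = compare_conditions(active_sets[a], active_sets[b]).sizes()
            venn["condition_a"] = a
            venn["condition_b"] = b

        if config.gene_stats is not None:
            neighborhoods = _stage("reporter")(build_neighborhoods)(model)
            stats_map = (
                config.gene_stats
                if isinstance(config.gene_stats, dict)
                else {c: config.gene_stats for c in config.conditions}
            )
            for cond, path in stats_map.items():
                gene_stats = _stage("reporter")(read_gene_stats)(path)
                result = _stage("reporter")(reporter_scores)(
                    neighborhoods,
                    gene_stats,
                    n_samples=config.n_samples,
                    seed=config.seed,
                )
                result.to_frame().to_csv(
                    out_dir / f"reporters_{cond}.tsv", sep="\t", index=False
                )
                sig = significant_reporters(result, config.alpha)
                reporters[cond] = {
                    "n_significant_up": len(sig["up"]),
                    "n_significant_down": len(sig["down"]),
                    "significant_up": sig["up"],
                    "significant_down": sig["down"],
                }
    except PipelineError as exc:
        failed = exc.stage
        manifest = RunManifest(
            config=asdict(config),
            model_census=model_census,
            per_condition=per_condition,
            venn=venn,
            reporters=reporters,
            version=__version__,
            started=started,
            finished=time.time(),
            failed_stage=f"FAILED:{failed}",
        )
        manifest.to_json(out_dir / "manifest.json")
        raise

    manifest = RunManifest(
        config=asdict(config),
        model_census=model_census,
        per_condition=per_condition,
        venn=venn,
        reporters=reporters,
        version=__version__,
        started=started,
        finished=time.time(),
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
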