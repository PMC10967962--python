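"""FPKM expression tables, percentile thresholds, reaction-level scores.

The integration threshold x_threshold is a percentile (default the 50th,
"P50") of the expression values of the model's metabolic genes under one
condition.  Gene expression is lifted onto reactions (x_i) either by
taking the maximum over the reaction's genes — matching the assumption
that a reaction is active once at least one associated gene is expressed —
or by a GPR-aware rule where enzyme complexes (AND) take the minimum
subunit expression and isozymes (OR) the maximum.

Genes present in the model but absent from the FPKM table are left
unscored rather than zeroed: absence of evidence carries no penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from tigsmm.model_io import GprExpr, MetabolicModel

__all__ = [
    "ExpressionProfile",
    "ThresholdConfig",
    "ReactionExpression",
    "ExpressionBins",
    "read_fpkm",
    "write_fpkm",
    "compute_threshold",
    "map_expression",
    "bin_expression",
]


@dataclass
class ExpressionProfile:
    """FPKM values for one condition (e.g. "LG" light–glucose)."""

    condition: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        for gene, fpkm in self.values.items():
            if fpkm < 0 or math.isnan(fpkm):
                raise ValueError(
                    f"negative or NaN FPKM for gene {gene!r} in condition "
                    f"{self.condition!r}: {fpkm}"
                )


@dataclass
class ThresholdConfig:
    """How x_threshold is derived from a profile.

    ``population`` selects which genes enter the percentile: the model's
    metabolic genes (default — the integrated model contains only those)
    or every gene in the table.
    """

    percentile: float = 50.0
    population: str = "metabolic_genes"  # or "all_genes"

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError(f"percentile must be in [0, 100], got {self.percentile}")
        if self.population not in ("metabolic_genes", "all_genes"):
            raise ValueError(f"unknown population {self.population!r}")


@dataclass
class ReactionExpression:
    """Reaction-level expression x_i.

    ``values`` holds scored reactions only; a reaction is unscored iff it
    has no GPR or none of its genes appear in the profile.
    ``reaction_ids`` lists every reaction of the model, scored or not.
    """

    values: Dict[str, float]
    reaction_ids: List[str]
    mapping_rule: str = "max_over_genes"

    def is_scored(self, rxn_id: str) -> bool:
        return rxn_id in self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "x_i": [self.values.get(r, np.nan) for r in self.reaction_ids],
                "scored": [r in self.values for r in self.reaction_ids],
            }
        )


@dataclass
class ExpressionBins:
    """Gene counts in the conventional FPKM magnitude bins."""

    counts: Dict[str, int]
    zero: int
    n_genes: int

    @property
    def fraction_expressed(self) -> float:
        return (self.n_genes - self.zero) / self.n_genes if self.n_genes else math.nan


def read_fpkm(path) -> List[ExpressionProfile]:
    """Read a TSV with a ``gene_id`` column and one column per condition.

    Raises on duplicate gene rows, non-numeric cells and negative FPKM.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id plus at least one condition column")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        dups = sorted(genes[genes.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene rows: {dups[:5]}")
    profiles = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), gene_col].iloc[0]
            raise ValueError(f"{path}: non-numeric FPKM for gene {bad!r} in {col!r}")
        if (vals < 0).any():
            bad = df.loc[vals < 0, gene_col].iloc[0]
            raise ValueError(f"{path}: negative FPKM for gene {bad!r} in {col!r}")
        profiles.append(
            ExpressionProfile(condition=str(col), values=dict(zip(genes, vals.astype(float))))
        )
    return profiles


def write_fpkm(profiles: List[ExpressionProfile], path) -> Path:
    """Write profiles to the TSV layout :func:`read_fpkm` expects."""
    genes = sorted(set().union(*(p.values.keys() for p in profiles)))
    df = pd.DataFrame({"gene_id": genes})
    for p in profiles:
        df[p.condition] = [p.values.get(g, 0.0) for g in genes]
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def compute_threshold(
    profile: ExpressionProfile,
    model: Optional[MetabolicModel] = None,
    config: Optional[ThresholdConfig] = None,
) -> float:
    """x_threshold: the configured percentile of the selected FPKM values,
    with linear interpolation between order statistics."""
    config = config or ThresholdConfig()
    if config.population == "metabolic_genes":
        if model is None:
            raise ValueError("metabolic_genes population requires a model")
        pool = [v for g, v in profile.values.items() if g in model.genes]
    else:
        pool = list(profile.values.values())
    if not pool:
        raise ValueError(
            f"empty gene population for threshold in condition {profile.condition!r}"
        )
    return float(np.percentile(pool, config.percentile))


def _eval_gpr(gpr: GprExpr, values: Dict[str, float]) -> Optional[float]:
    """GPR-aware score: AND → min, OR → max, over scorable children only."""
    if gpr.kind == "gene":
        return values.get(gpr.gene)
    scores = [s for s in (_eval_gpr(c, values) for c in gpr.children) if s is not None]
    if not scores:
        return None
    return min(scores) if gpr.kind == "and" else max(scores)


def map_expression(
    model: MetabolicModel,
    profile: ExpressionProfile,
    rule: str = "max_over_genes",
) -> ReactionExpression:
    """Lift gene FPKM onto reactions as x_i.

    ``max_over_genes`` takes the maximum over all genes of the reaction;
    ``gpr_aware`` evaluates the GPR tree with AND → min and OR → max.
    Reactions without a GPR, or whose genes are all missing from the
    profile, stay unscored.
    """
    if rule not in ("max_over_genes", "gpr_aware"):
        raise ValueError(f"unknown mapping rule {rule!r}")
    values: Dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        if rule == "max_over_genes":
            scores = [profile.values[g] for g in rxn.genes() if g in profile.values]
            score = max(scores) if scores else None
        else:
            score = _eval_gpr(rxn.gpr, profile.values)
        if score is not None:
            values[rxn.id] = float(score)
    return ReactionExpression(
        values=values, reaction_ids=model.reaction_ids(), mapping_rule=rule
    )


_BIN_EDGES = (1.0, 10.0, 100.0)
_BIN_LABELS = ("sub_1", "1_10", "10_100", "ge_100")


def bin_expression(profile: ExpressionProfile, expressed_floor: float = 0.0) -> ExpressionBins:
    """Count genes in the magnitude bins [floor, 1), [1, 10), [10, 100),
    [100, ∞); genes below the floor (not expressed, FPKM ≤ floor for the
    default floor of 0) are reported separately as ``zero``."""
    vals = np.array(list(profile.values.values()), dtype=float)
    if expressed_floor > 0:
        expressed = vals >= expressed_floor
    else:
        expressed = vals > 0
    counts = {label: 0 for label in _BIN_LABELS}
    ev = vals[expressed]
    counts["sub_1"] = int(np.sum(ev < 1.0))
    counts["1_10"] = int(np.sum((ev >= 1.0) & (ev < 10.0)))
    counts["10_100"] = int(np.sum((ev >= 10.0) & (ev < 100.0)))
    counts["ge_100"] = int(np.sum(ev >= 100.0))
    return ExpressionBins(counts=counts, zero=int(np.sum(~expressed)), n_genes=len(vals))
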