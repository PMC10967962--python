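"""GIMME: Gene Inactivity Moderated by Metabolism and Expression.

Given reaction-level expression x_i and a threshold x_threshold, each
reaction receives a penalty

    c_i = x_threshold − x_i   if x_threshold > x_i, else 0,

and the context-specific flux state minimizes the total penalized
absolute flux

    minimize  Σ_i c_i · |v_i|
    s.t.      S·v = 0,  lb ≤ v ≤ ub,  v_biomass ≥ f · μ*

where μ* is the FBA growth maximum and f the required growth fraction.
Reactions without expression evidence carry zero penalty.  The optimum's
objective value is the inconsistency score: how much below-threshold
flux the data force the model to keep.

The absolute value is handled exactly by splitting each reversible
penalized flux into non-negative forward/backward parts — valid because
all c_i ≥ 0.  A brute-force oracle (:func:`enumerate_gimme_oracle`)
re-solves tiny instances by enumerating sign orthants and LP vertices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from tigsmm.expression import ReactionExpression, ThresholdConfig
from tigsmm.fba import (
    ORACLE_MAX_REACTIONS,
    brute_force_lp,
    build_stoichiometric_matrix,
    enumerate_vertices_oracle,
    solve_fba,
)
from tigsmm.model_io import MetabolicModel

__all__ = [
    "PenaltyVector",
    "GimmeConfig",
    "GimmeSolution",
    "compute_penalties",
    "solve_gimme",
    "context_reaction_states",
    "enumerate_gimme_oracle",
]


@dataclass
class PenaltyVector:
    """Per-reaction penalties c_i ≥ 0; unscored reactions carry 0."""

    values: Dict[str, float]

    def __post_init__(self) -> None:
        for rxn_id, c in self.values.items():
            if c < 0:
                raise ValueError(f"negative penalty for reaction {rxn_id!r}: {c}")


@dataclass
class GimmeConfig:
    """Knobs of the integration.

    ``growth_fraction`` is the fraction f of the FBA maximum the context
    model must still achieve; 1.0 pins growth at the unconstrained
    optimum, the replication profile for studies that use the FBA maximum
    itself as the boundary.  ``zero_tolerance`` separates numerical LP
    noise from biologically active flux.
    """

    growth_fraction: float = 0.90
    zero_tolerance: float = 1e-6
    threshold_config: ThresholdConfig = field(default_factory=ThresholdConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.growth_fraction <= 1.0:
            raise ValueError(
                f"growth_fraction must be in (0, 1], got {self.growth_fraction}"
            )


@dataclass
class GimmeSolution:
    """Context-specific flux state with its inconsistency score."""

    status: str
    fluxes: Dict[str, float] = field(default_factory=dict)
    inconsistency_score: float = math.nan
    growth_rate: float = math.nan
    fba_maximum: float = math.nan


def compute_penalties(
    rxn_expr: ReactionExpression, x_threshold: float
) -> PenaltyVector:
    """c_i = max(0, x_threshold − x_i) for scored reactions, 0 otherwise."""
    if not math.isfinite(x_threshold):
        raise ValueError(f"x_threshold must be finite, got {x_threshold}")
    values = {}
    for rxn_id in rxn_expr.reaction_ids:
        if rxn_expr.is_scored(rxn_id):
            values[rxn_id] = max(0.0, x_threshold - rxn_expr.values[rxn_id])
        else:
            values[rxn_id] = 0.0
    return PenaltyVector(values=values)


def _score(penalties: Dict[str, float], fluxes: Dict[str, float]) -> float:
    return float(sum(penalties.get(r, 0.0) * abs(v) for r, v in fluxes.items()))


def solve_gimme(
    model: MetabolicModel,
    penalties: PenaltyVector,
    config: Optional[GimmeConfig] = None,
) -> GimmeSolution:
    """Two-phase GIMME solve.

    Phase 1 finds the FBA growth maximum μ*; phase 2 raises the biomass
    lower bound to f·μ* and minimizes Σ c_i·|v_i| with forward/backward
    flux splitting for reversible penalized reactions.
    """
    config = config or GimmeConfig()
    unknown = set(penalties.values) - set(model.reaction_ids())
    if unknown:
        raise KeyError(f"penalties reference unknown reactions: {sorted(unknown)[:5]}")

    phase1 = solve_fba(model)
    if phase1.status != "optimal":
        return GimmeSolution(status=phase1.status)
    mu_star = phase1.objective_value

    floored = model.copy()
    biomass = floored.get_reaction(floored.biomass_id)
    biomass.lb = max(biomass.lb, config.growth_fraction * mu_star)

    S, _, _ = build_stoichiometric_matrix(floored)
    S = S.tocsc()
    n = len(floored.reactions)
    c_pen = np.array([penalties.values.get(r.id, 0.0) for r in floored.reactions])
    lb = np.array([r.lb for r in floored.reactions])
    ub = np.array([r.ub for r in floored.reactions])

    # Column layout: one column per reaction; reversible reactions get an
    # extra mirrored column for the backward direction.
    spanning = (lb < 0) & (ub > 0)
    cols = [S]
    obj = np.where(lb >= 0, c_pen, -c_pen)  # |v| = v or -v when sign is fixed
    obj[spanning] = c_pen[spanning]  # forward part
    lo = lb.copy()
    hi = ub.copy()
    lo[spanning] = 0.0
    back_idx = np.where(spanning)[0]
    if back_idx.size:
        cols.append(-S[:, back_idx])
        obj = np.concatenate([obj, c_pen[back_idx]])
        lo = np.concatenate([lo, np.zeros(back_idx.size)])
        hi = np.concatenate([hi, -lb[back_idx]])
    A = sp.hstack(cols, format="csr")

    res = linprog(
        obj,
        A_eq=A,
        b_eq=np.zeros(A.shape[0]),
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "infeasible")
    if status != "optimal":
        return GimmeSolution(status=status, fba_maximum=mu_star)

    x = np.asarray(res.x)
    v = x[:n].copy()
    v[back_idx] -= x[n:]
    fluxes = {r.id: float(v[i]) for i, r in enumerate(floored.reactions)}
    return GimmeSolution(
        status="optimal",
        fluxes=fluxes,
        inconsistency_score=_score(penalties.values, fluxes),
        growth_rate=fluxes[floored.biomass_id],
        fba_maximum=mu_star,
    )


def context_reaction_states(
    solution: GimmeSolution, zero_tolerance: float = 1e-6
) -> Dict[str, str]:
    """Classify each reaction as "active" (|v| above tolerance) or
    "inactive" (flux indistinguishable from zero)."""
    if solution.status != "optimal":
        raise ValueError(f"cannot classify a {solution.status} solution")
    return {
        rxn_id: "active" if abs(v) > zero_tolerance else "inactive"
        for rxn_id, v in solution.fluxes.items()
    }


def enumerate_gimme_oracle(
    model: MetabolicModel,
    penalties: PenaltyVector,
    config: Optional[GimmeConfig] = None,
    max_spanning: int = 6,
) -> GimmeSolution:
    """Brute-force phase-2 optimum for tiny models.

    Phase 1 uses the vertex-enumeration FBA oracle.  Phase 2 observes that
    Σ c_i·|v_i| is linear within each sign orthant of the penalized
    reversible fluxes, so it enumerates every such orthant, restricts the
    bounds accordingly, and minimizes the resulting linear objective by
    vertex enumeration; the best orthant wins.  Entirely independent of
    the HiGHS code path.
    """
    config = config or GimmeConfig()
    n = len(model.reactions)
    if n > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"GIMME oracle limited to {ORACLE_MAX_REACTIONS} reactions, model has {n}"
        )
    phase1 = enumerate_vertices_oracle(model)
    if phase1.status != "optimal":
        return GimmeSolution(status=phase1.status)
    mu_star = phase1.objective_value

    floored = model.copy()
    biomass = floored.get_reaction(floored.biomass_id)
    biomass.lb = max(biomass.lb, config.growth_fraction * mu_star)

    S, _, _ = build_stoichiometric_matrix(floored)
    A = S.toarray()
    c_pen = np.array([penalties.values.get(r.id, 0.0) for r in floored.reactions])
    lb = np.array([r.lb for r in floored.reactions])
    ub = np.array([r.ub for r in floored.reactions])

    split = np.where((c_pen > 0) & (lb < 0) & (ub > 0))[0]
    if split.size > max_spanning:
        raise ValueError(
            f"too many reversible penalized reactions for orthant enumeration: "
            f"{split.size} > {max_spanning}"
        )

    best: Optional[GimmeSolution] = None
    feasible_seen = False
    for signs in itertools.product((1.0, -1.0), repeat=split.size):
        lo = lb.copy()
        hi = ub.copy()
        c_lin = np.where(lb >= 0, c_pen, -c_pen)
        for idx, s in zip(split, signs):
            if s > 0:
                lo[idx] = 0.0
                c_lin[idx] = c_pen[idx]
            else:
                hi[idx] = 0.0
                c_lin[idx] = -c_pen[idx]
        status, x, _ = brute_force_lp(
            c_lin, A, np.zeros(A.shape[0]), lo, hi, sense="minimize"
        )
        if status != "optimal":
            continue
        feasible_seen = True
        fluxes = {r.id: float(x[i]) for i, r in enumerate(floored.reactions)}
        score = _score(penalties.values, fluxes)
        if best is None or score < best.inconsistency_score - 1e-12:
            best = GimmeSolution(
                status="optimal",
                fluxes=fluxes,
                inconsistency_score=score,
                growth_rate=fluxes[floored.biomass_id],
                fba_maximum=mu_star,
            )
    if best is None:
        return GimmeSolution(
            status="infeasible" if not feasible_seen else "optimal",
            fba_maximum=mu_star,
        )
    return best
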