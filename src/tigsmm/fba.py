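"""Flux balance analysis: stoichiometric matrix assembly and LP solving.

FBA maximizes an objective flux (usually biomass) over the steady-state
polytope {v : S·v = 0, lb ≤ v ≤ ub}.  The production path goes through
``scipy.optimize.linprog`` (HiGHS); tiny models (≤ 12 reactions) can also
be solved by :func:`enumerate_vertices_oracle`, a brute-force enumeration
of basic feasible solutions that serves as an independent check on the LP
solver.

Sign convention: exchange reactions are written "metabolite ↔ ∅", so
uptake is a negative exchange flux and all quoted uptake rates are
magnitudes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from tigsmm.model_io import MetabolicModel, ReactionKind

__all__ = [
    "LpProblem",
    "FluxSolution",
    "UptakeConstraint",
    "build_stoichiometric_matrix",
    "apply_uptake",
    "solve_fba",
    "growth_error_percent",
    "enumerate_vertices_oracle",
    "brute_force_lp",
]

FEASIBILITY_TOL = 1e-6
ORACLE_MAX_REACTIONS = 12
_BIG = 1e7  # clamp for infinite bounds inside the brute-force oracle


@dataclass
class LpProblem:
    """A linear program in equality standard form with box bounds."""

    objective_coeffs: np.ndarray
    equality_matrix: sp.spmatrix
    equality_rhs: np.ndarray
    var_bounds: List[Tuple[float, float]]
    sense: str = "maximize"  # or "minimize"

    def __post_init__(self) -> None:
        n = len(self.objective_coeffs)
        if self.equality_matrix.shape[1] != n or len(self.var_bounds) != n:
            raise ValueError("inconsistent LP dimensions")
        if self.equality_matrix.shape[0] != len(self.equality_rhs):
            raise ValueError("inconsistent equality dimensions")
        for lb, ub in self.var_bounds:
            if lb > ub:
                raise ValueError(f"variable bound lb {lb} > ub {ub}")


@dataclass
class FluxSolution:
    """Outcome of an FBA solve.

    ``fluxes`` maps reaction id to flux (mmol gDW⁻¹ h⁻¹).  For an optimal
    solution ‖S·v‖∞ ≤ 1e-6 and every flux lies within its bounds up to
    1e-9.
    """

    status: str  # "optimal" | "infeasible" | "unbounded"
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: float = math.nan


@dataclass(frozen=True)
class UptakeConstraint:
    """Cap the uptake of one exchange reaction at ``rate`` (a magnitude)."""

    exchange_reaction_id: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"uptake rate must be non-negative, got {self.rate}")


def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> Tuple[sp.csr_matrix, Dict[str, int], Dict[str, int]]:
    """Assemble S with rows in model metabolite order and columns in model
    reaction order; entry (j, i) is the signed coefficient of metabolite j
    in reaction i.  Returns (S, metabolite_index, reaction_index)."""
    met_index = {m.id: j for j, m in enumerate(model.metabolites)}
    rxn_index = {r.id: i for i, r in enumerate(model.reactions)}
    rows: List[int] = []
    cols: List[int] = []
    data: List[float] = []
    for i, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoich.items():
            rows.append(met_index[met_id])
            cols.append(i)
            data.append(coeff)
    S = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return S, met_index, rxn_index


def apply_uptake(
    model: MetabolicModel,
    constraints: Sequence[UptakeConstraint] = (),
    open_nutrients: Sequence[str] = (),
) -> MetabolicModel:
    """Return a copy of ``model`` with the growth medium set.

    Every exchange reaction is first closed to secretion-only (lb = 0);
    ``open_nutrients`` (e.g. ammonium, phosphate, sulfate, water, protons)
    are reopened to unconstrained uptake (lb = −1000); each constrained
    carbon source gets lb = −rate.  Upper bounds are left untouched.
    """
    out = model.copy()
    exchange_ids = set(out.exchange_ids())
    for rxn in out.reactions:
        if rxn.kind == ReactionKind.EXCHANGE:
            rxn.lb = 0.0
    for ex_id in open_nutrients:
        if ex_id not in exchange_ids:
            raise KeyError(f"unknown exchange reaction {ex_id!r}")
        out.get_reaction(ex_id).lb = -1000.0
    for con in constraints:
        if con.exchange_reaction_id not in exchange_ids:
            raise KeyError(f"unknown exchange reaction {con.exchange_reaction_id!r}")
        out.get_reaction(con.exchange_reaction_id).lb = -con.rate
    return out


def _status_from_linprog(res) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "infeasible")


def solve_fba(
    model: MetabolicModel, objective_reaction_id: Optional[str] = None
) -> FluxSolution:
    """Maximize the flux of ``objective_reaction_id`` (default: the model's
    biomass reaction) over the steady-state polytope.

    Infeasible or unbounded problems are reported in ``status``; fluxes
    are only populated for optimal solves.
    """
    obj_id = objective_reaction_id or model.biomass_id
    S, _, rxn_index = build_stoichiometric_matrix(model)
    if obj_id not in rxn_index:
        raise KeyError(f"objective reaction {obj_id!r} not in model")
    n = len(model.reactions)
    c = np.zeros(n)
    c[rxn_index[obj_id]] = -1.0  # linprog minimizes
    bounds = [(r.lb, r.ub) for r in model.reactions]
    if n == 0:
        return FluxSolution(status="optimal", fluxes={}, objective_value=0.0)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _status_from_linprog(res)
    if status != "optimal":
        return FluxSolution(status=status)
    v = np.asarray(res.x)
    residual = np.abs(S @ v).max() if S.shape[0] else 0.0
    if residual > FEASIBILITY_TOL:
        raise RuntimeError(f"LP solution violates steady state: |S v| = {residual:g}")
    fluxes = {r.id: float(v[i]) for i, r in enumerate(model.reactions)}
    return FluxSolution(
        status="optimal", fluxes=fluxes, objective_value=float(-res.fun)
    )


def growth_error_percent(predicted: float, observed: float) -> float:
    """Relative growth prediction error, |predicted − observed| / observed × 100."""
    if observed <= 0:
        raise ValueError(f"observed growth rate must be positive, got {observed}")
    return abs(predicted - observed) / observed * 100.0


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_lp(
    c: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "maximize",
    tol: float = 1e-6,
) -> Tuple[str, Optional[np.ndarray], float]:
    """Solve a small box-bounded equality-form LP by enumerating basic
    feasible solutions.

    Every vertex of {x : A x = b, lb ≤ x ≤ ub} has at least n − rank(A)
    coordinates at a bound; the enumeration fixes each size-(n − rank)
    subset of variables at every combination of its bounds and solves the
    remaining square system.  Infinite bounds are clamped to ±1e7; an
    optimum that rests on a clamped coordinate of an originally infinite
    bound is reported as unbounded.

    Returns (status, x, objective) with status in
    {"optimal", "infeasible", "unbounded"}.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(c)
    lb = np.asarray(lb, dtype=float).copy()
    ub = np.asarray(ub, dtype=float).copy()
    inf_lb = np.isinf(lb)
    inf_ub = np.isinf(ub)
    lb[inf_lb] = -_BIG
    ub[inf_ub] = _BIG

    sign = 1.0 if sense == "maximize" else -1.0
    r = np.linalg.matrix_rank(A) if A.size else 0
    k = n - r

    # Track the best vertex overall and the best one not resting on a
    # clamped (originally infinite) bound; the LP is unbounded only when
    # clamped vertices strictly beat every clean vertex.
    best_obj = -np.inf
    best_x: Optional[np.ndarray] = None
    best_clean_obj = -np.inf
    best_clean_x: Optional[np.ndarray] = None

    feas_tol = tol * max(1.0, float(np.abs(b).max()) if b.size else 0.0)

    for fixed_cols in itertools.combinations(range(n), k):
        fixed = list(fixed_cols)
        free = [i for i in range(n) if i not in fixed_cols]
        A_free = A[:, free] if free else np.zeros((A.shape[0], 0))
        # all 2^k corner assignments of the fixed variables, one lstsq call
        if fixed:
            choices = np.array(
                list(itertools.product(*[(lb[i], ub[i]) for i in fixed]))
            ).T  # (k, 2^k)
            rhs = b[:, None] - A[:, fixed] @ choices
        else:
            choices = np.zeros((0, 1))
            rhs = b[:, None]
        if free:
            sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            resid = np.abs(A_free @ sol - rhs).max(axis=0) if A.size else np.zeros(rhs.shape[1])
        else:
            sol = np.zeros((0, rhs.shape[1]))
            resid = np.abs(rhs).max(axis=0) if rhs.size else np.zeros(rhs.shape[1])
        for col in range(rhs.shape[1]):
            if resid[col] > feas_tol:
                continue
            x = np.empty(n)
            if fixed:
                x[fixed] = choices[:, col]
            if free:
                x[free] = sol[:, col]
            if np.any(x < lb - feas_tol) or np.any(x > ub + feas_tol):
                continue
            obj = sign * float(c @ x)
            if obj > best_obj + 1e-12:
                best_obj = obj
                best_x = x.copy()
            touches_clamp = bool(
                np.any(inf_lb & (x < -_BIG + 1.0)) or np.any(inf_ub & (x > _BIG - 1.0))
            )
            if not touches_clamp and obj > best_clean_obj + 1e-12:
                best_clean_obj = obj
                best_clean_x = x.copy()

    if best_x is None:
        return "infeasible", None, math.nan
    if best_clean_x is not None and best_obj <= best_clean_obj + tol * max(
        1.0, abs(best_clean_obj)
    ):
        return "optimal", best_clean_x, sign * best_clean_obj
    return "unbounded", None, math.inf if sense == "maximize" else -math.inf


def enumerate_vertices_oracle(
    model: MetabolicModel, objective_reaction_id: Optional[str] = None
) -> FluxSolution:
    """Exact FBA optimum by brute-force vertex enumeration.

    Independent of :func:`solve_fba` (no LP solver involved); refuses
    models with more than 12 reactions.
    """
    n = len(model.reactions)
    if n > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"vertex-enumeration oracle limited to {ORACLE_MAX_REACTIONS} "
            f"reactions, model has {n}"
        )
    obj_id = objective_reaction_id or model.biomass_id
    S, _, rxn_index = build_stoichiometric_matrix(model)
    if obj_id not in rxn_index:
        raise KeyError(f"objective reaction {obj_id!r} not in model")
    c = np.zeros(n)
    c[rxn_index[obj_id]] = 1.0
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    status, x, obj = brute_force_lp(
        c, S.toarray(), np.zeros(S.shape[0]), lb, ub, sense="maximize"
    )
    if status != "optimal":
        return FluxSolution(status=status)
    fluxes = {r.id: float(x[i]) for i, r in enumerate(model.reactions)}
    return FluxSolution(status="optimal", fluxes=fluxes, objective_value=obj)
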