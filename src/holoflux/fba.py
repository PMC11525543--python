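"""Flux balance analysis: biomass maximization, feasibility, requirement search.

The LP maximizes the biomass-reaction flux subject to steady state
(``S v = 0`` over all metabolites, extracellular pools included — boundary
turnover flows through exchange reactions), reaction bounds, and per-metabolite
uptake limits applied to exchange reactions. Among the usually degenerate
optima a second parsimonious stage picks the unique-by-construction solution
minimizing the total absolute flux at fixed optimal growth, so repeated solves
of the same instance return identical flux vectors.

Tolerances: LP feasibility/optimality are left at HiGHS defaults (~1e-9);
fluxes with magnitude below ``ZERO_TOL`` (1e-9) are reported as exact zeros,
which makes "growth = 0" assertions exact-testable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, hstack, vstack, eye

from .netcore import MetabolicModel, validate_model

__all__ = [
    "UptakeBounds",
    "FluxSolution",
    "FBAProblem",
    "solve_fba",
    "growth_feasible",
    "minimal_requirement",
    "ZERO_TOL",
]

ZERO_TOL = 1e-9
#: treat model bounds at or beyond this magnitude as unconstrained
BIG_BOUND = 1e5

UptakeBounds = Mapping[str, float]


@dataclass
class FluxSolution:
    """Result of one FBA solve.

    ``growth_rate`` is the biomass-reaction flux (h^-1); ``fluxes`` maps every
    reaction id to its parsimonious flux; ``status`` is one of ``optimal``,
    ``infeasible``, ``unbounded``. On non-optimal status growth and fluxes are
    zero. ``diagnostic`` carries solver context (e.g. reactions participating
    in an unbounded cycle).
    """

    growth_rate: float
    fluxes: dict[str, float]
    status: str
    objective: str = "max biomass, then min sum |v| (parsimonious)"
    diagnostic: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "growth_rate": self.growth_rate, "status": self.status,
            "objective": self.objective, "fluxes": self.fluxes,
        }, indent=1, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["reaction_id\tflux"]
        lines += [f"{rid}\t{v!r}" for rid, v in sorted(self.fluxes.items())]
        return "\n".join(lines) + "\n"


class FBAProblem:
    """Pre-assembled LP data for one model; reusable across many solves."""

    def __init__(self, model: MetabolicModel, validate: bool = True):
        if validate:
            report = validate_model(model)
            if not report.valid:
                raise ValueError("invalid model: " + "; ".join(report.violations))
        self.model = model
        self.rxn_ids = [r.id for r in model.reactions]
        self.n = len(self.rxn_ids)
        met_ids = [m.id for m in model.metabolites]
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for met_id, coef in r.stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        self.S = csr_matrix((vals, (rows, cols)), shape=(len(met_ids), self.n))
        self.lb = np.array([r.lower_bound for r in model.reactions])
        self.ub = np.array([r.upper_bound for r in model.reactions])
        self.biomass_j = self.rxn_ids.index(model.biomass_reaction_id)
        # exchange column index per exchanged metabolite, with its coefficient
        self.exchange_cols: dict[str, tuple[int, float]] = {}
        for j, r in enumerate(model.reactions):
            if r.kind == "exchange" and len(r.stoichiometry) == 1:
                met_id, coef = next(iter(r.stoichiometry.items()))
                self.exchange_cols[met_id] = (j, coef)
        self._pfba_parts = None

    def effective_bounds(self, uptake: UptakeBounds) -> tuple[np.ndarray, np.ndarray]:
        """Apply uptake limits: for exchange of m, allowed uptake flux is
        uptake[m] (0 when absent), i.e. lb = max(model lb, -uptake)."""
        lb = self.lb.copy()
        ub = self.ub.copy()
        for met_id, (j, coef) in self.exchange_cols.items():
            u = float(uptake.get(met_id, 0.0))
            if u < 0 or not math.isfinite(u):
                raise ValueError(f"uptake bound for {met_id} must be finite and >= 0")
            if coef < 0:  # export-positive convention: uptake = negative flux
                lb[j] = max(lb[j], -u)
            else:  # import-positive (tolerated): uptake = positive flux
                ub[j] = min(ub[j], u)
        return lb, ub

    def solve(self, uptake: UptakeBounds, parsimonious: bool = True) -> FluxSolution:
        lb, ub = self.effective_bounds(uptake)
        c = np.zeros(self.n)
        c[self.biomass_j] = -1.0
        res = linprog(c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status == 2:
            return FluxSolution(0.0, {rid: 0.0 for rid in self.rxn_ids}, "infeasible")
        if res.status == 3:
            return FluxSolution(0.0, {rid: 0.0 for rid in self.rxn_ids}, "unbounded",
                                diagnostic=self._unbounded_cycle(lb, ub))
        if res.status != 0:
            raise RuntimeError(f"LP solver failure: {res.message}")
        growth = float(-res.fun)
        v = res.x
        if parsimonious:
            v = self._parsimonious(lb, ub, growth)
        growth = float(v[self.biomass_j])
        v = np.where(np.abs(v) < ZERO_TOL, 0.0, v)
        growth = 0.0 if abs(growth) < ZERO_TOL else growth
        return FluxSolution(growth, dict(zip(self.rxn_ids, v.tolist())), "optimal")

    def _parsimonious(self, lb: np.ndarray, ub: np.ndarray, growth: float) -> np.ndarray:
        """min sum |v_i| over non-biomass reactions at fixed optimal growth."""
        if self._pfba_parts is None:
            n = self.n
            I = eye(n, format="csr")
            # a_i >= |v_i|:  v - a <= 0  and  -v - a <= 0
            A_ub = vstack([hstack([I, -I]), hstack([-I, -I])], format="csr")
            A_eq = hstack([self.S, csr_matrix(self.S.shape)], format="csr")
            self._pfba_parts = (A_ub, A_eq)
        A_ub, A_eq = self._pfba_parts
        n = self.n
        lb2 = lb.copy()
        ub2 = ub.copy()
        # keep growth within solver tolerance of its optimum; a dominant
        # objective reward pins it back to the optimum exactly
        slack = 1e-6 * max(1.0, abs(growth))
        lb2[self.biomass_j] = max(lb[self.biomass_j], growth - slack)
        ub2[self.biomass_j] = min(ub[self.biomass_j], growth)
        c = np.concatenate([np.zeros(n), np.ones(n)])
        c[self.biomass_j] = -1e5
        c[n + self.biomass_j] = 0.0
        bounds = np.column_stack([
            np.concatenate([lb2, np.zeros(n)]),
            np.concatenate([ub2, np.full(n, np.inf)]),
        ])
        res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * n),
                      A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                      bounds=bounds, method="highs")
        if res.status != 0:  # pragma: no cover - safety net
            raise RuntimeError(f"parsimonious stage failed: {res.message}")
        return res.x[:n]

    def _unbounded_cycle(self, lb: np.ndarray, ub: np.ndarray) -> str:
        """Re-solve with huge finite bounds; reactions pinned at them form the
        unbounded flux cycle."""
        cap = 1e9
        lb2 = np.maximum(lb, -cap)
        ub2 = np.minimum(ub, cap)
        c = np.zeros(self.n)
        c[self.biomass_j] = -1.0
        res = linprog(c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([lb2, ub2]), method="highs")
        if res.status != 0:
            return "unbounded objective; cycle could not be isolated"
        member = [rid for rid, v in zip(self.rxn_ids, res.x) if abs(v) > cap * 1e-3]
        return "unbounded cycle through reactions: " + ", ".join(member)


def solve_fba(model: MetabolicModel, uptake: UptakeBounds,
              parsimonious: bool = True) -> FluxSolution:
    """Maximize biomass flux of ``model`` under ``uptake`` limits.

    ``uptake`` maps extracellular metabolite ids to the maximum uptake flux
    (mmol gDW^-1 h^-1, >= 0); metabolites absent from the map cannot be taken
    up. Secretion is limited only by the model's own exchange upper bounds.
    """
    return FBAProblem(model).solve(uptake, parsimonious=parsimonious)


def growth_feasible(model: MetabolicModel, uptake: UptakeBounds) -> bool:
    """True iff FBA growth exceeds the reported-zero threshold (1e-9)."""
    return solve_fba(model, uptake, parsimonious=False).growth_rate > ZERO_TOL


def minimal_requirement(model: MetabolicModel, uptake: UptakeBounds,
                        target_metabolite: str, growth_floor: float,
                        rel_tol: float = 1e-4) -> float:
    """Smallest max-uptake of ``target_metabolite`` reaching ``growth_floor``.

    Other uptake bounds are held fixed. Bisection on [0, 1e6]; returns
    ``math.inf`` if even the bracket top cannot reach the floor (e.g. an
    auxotrophy that no amount of the target metabolite rescues).
    """
    if growth_floor <= 0:
        raise ValueError("growth_floor must be > 0")
    problem = FBAProblem(model)

    def growth_at(u: float) -> float:
        bounds = dict(uptake)
        bounds[target_metabolite] = u
        return problem.solve(bounds, parsimonious=False).growth_rate

    lo, hi = 0.0, 1e6
    if growth_at(hi) < growth_floor:
        return math.inf
    if growth_at(lo) >= growth_floor:
        return 0.0
    while (hi - lo) > rel_tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if growth_at(mid) >= growth_floor:
            hi = mid
        else:
            lo = mid
    return hi
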