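"""Flux balance analysis and the wild-type reference flux distribution.

``solve_fba`` optimizes a single reaction flux over the steady-state polytope
(mass balance, bounds, fixed uptake, optional biomass threshold, knockouts).
``wild_type_fluxes`` pins down the reference distribution ``w`` used by the
minimal-flux-change (ROOM-type) inner models: among all biomass-optimal flux
vectors it returns the one with minimal total absolute flux, so the reference
is unique and reproducible even when the biomass optimum is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FluxSolution, KnockoutDesign, MetabolicModel
from .solver import solve_lp

_ZERO_SNAP = 1e-9


@dataclass(frozen=True)
class WildTypeReference:
    """Reference (wild-type) fluxes ``w``: biomass-optimal, minimal total flux."""

    w: dict[str, float]

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.w[r.id] for r in model.reactions])


def _variable_bounds(model: MetabolicModel, design: KnockoutDesign | None) -> list[tuple[float, float]]:
    knocked = design.knocked if design is not None else frozenset()
    bounds = []
    for r in model.reactions:
        if r.id in knocked:
            bounds.append((0.0, 0.0))
        else:
            bounds.append(model.effective_bounds(r.id))
    return bounds


def solve_fba(
    model: MetabolicModel,
    objective_reaction: str,
    sense: str = "max",
    design: KnockoutDesign | None = None,
    enforce_biomass_min: bool = True,
) -> FluxSolution:
    """Optimize one reaction's flux subject to the steady-state constraints.

    Knocked reactions are clamped to zero flux; the uptake reaction is fixed
    at the model's uptake rate; ``v_biom >= biomass_min`` is enforced unless
    disabled.  Infeasibility/unboundedness is reported through the returned
    status, not raised.
    """
    if design is not None:
        design.validate_against(model)
    rids = model.reaction_ids()
    if objective_reaction not in rids:
        raise KeyError(objective_reaction)
    S, _ = model.stoichiometric_matrix()
    n = len(rids)
    c = np.zeros(n)
    c[rids.index(objective_reaction)] = 1.0
    A_ub = b_ub = None
    if enforce_biomass_min and model.biomass_min > 0:
        row = np.zeros((1, n))
        row[0, rids.index(model.biomass_reaction.id)] = -1.0
        A_ub, b_ub = row, np.array([-model.biomass_min])
    res = solve_lp(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_variable_bounds(model, design),
        sense=sense,
    )
    if not res.optimal:
        return FluxSolution(v={}, objective=None, status=res.status)
    v = {rid: _snap(res.x[j]) for j, rid in enumerate(rids)}
    return FluxSolution(v=v, objective=float(res.objective), status="optimal")


def _snap(x: float) -> float:
    return 0.0 if abs(x) < _ZERO_SNAP else float(x)


def wild_type_fluxes(model: MetabolicModel) -> WildTypeReference:
    """Two-stage LP: maximize biomass, then minimize total absolute flux.

    The secondary (parsimonious) stage removes the solver-vertex dependence a
    degenerate biomass optimum would otherwise leak into every downstream
    minimal-change computation.
    """
    stage1 = solve_fba(model, model.biomass_reaction.id, sense="max", enforce_biomass_min=False)
    if stage1.status != "optimal":
        raise ValueError(
            f"wild-type FBA is {stage1.status}; run validate_model for diagnostics"
        )
    vmax = stage1.objective
    rids = model.reaction_ids()
    n = len(rids)
    S, _ = model.stoichiometric_matrix()
    m = S.shape[0]
    # variables: v (n) then t (n) with t_j >= |v_j|
    A_eq = np.hstack([S, np.zeros((m, n))])
    biom = np.zeros(2 * n)
    biom[rids.index(model.biomass_reaction.id)] = 1.0  # v_biom = vmax, exactly
    A_eq = np.vstack([A_eq, biom])
    b_eq = np.concatenate([np.zeros(m), [vmax]])
    rows = []
    for j in range(n):
        r1 = np.zeros(2 * n)
        r1[j], r1[n + j] = 1.0, -1.0  # v_j - t_j <= 0
        rows.append(r1)
        r2 = np.zeros(2 * n)
        r2[j], r2[n + j] = -1.0, -1.0  # -v_j - t_j <= 0
        rows.append(r2)
    bounds = _variable_bounds(model, None) + [(0.0, None)] * n
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = solve_lp(
        c,
        A_ub=np.vstack(rows),
        b_ub=np.zeros(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        sense="min",
    )
    if not res.optimal:
        raise RuntimeError(f"parsimonious stage unexpectedly {res.status}")
    # snap round-off onto the flux bounds: a reference within 1e-8 of a bound
    # must sit exactly on it, or the (v_max - w) / (v_min - w) coefficients of
    # the flux-change constraints become pathologically small and the inner
    # duals explode
    w = {}
    for j, rid in enumerate(rids):
        lo, hi = model.effective_bounds(rid)
        val = _snap(res.x[j])
        if abs(val - lo) < 1e-8:
            val = lo
        elif abs(val - hi) < 1e-8:
            val = hi
        w[rid] = val
    return WildTypeReference(w=w)
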