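"""Optimistic (cooperative) bi-level baselines as single-level MILPs.

Both baselines maximize the target flux over knockout vectors ``z`` subject
to the cell responding with an inner-OPTIMAL flux distribution — the
cooperative assumption: among tied inner optima the formulation inherently
selects the one most favorable to the engineering objective.  The inner LP
is collapsed by strong duality into {primal feasibility + dual feasibility +
primal objective = dual objective}; the ``z``-dependent dual-objective terms
are big-M linearized like in the pessimistic module.
"""

from __future__ import annotations

import numpy as np

from .fba import WildTypeReference
from .inner import InnerProblem, build_inner
from .model import KnockoutDesign, MetabolicModel
from .pessimistic import BigMConfig, linearize_products
from .results import DesignResult
from .solver import MipBuilder, SolveResult


def _assemble_optimistic(
    inner: InnerProblem, K: int, M_dual: float, bigm: BigMConfig, exclude=()
) -> tuple[MipBuilder, dict]:
    model = inner.model
    n_x = inner.n_x
    m_eq, m_ub = inner.A.shape[0], inner.B.shape[0]
    n_kn = len(inner.knockable)
    M_flux = bigm.flux_bound(model)

    mb = MipBuilder()
    z = mb.add_vars("z", n_kn, lb=0, ub=1, integer=True)
    x = mb.add_vars("x", n_x, lb=-M_flux, ub=M_flux)
    nu = mb.add_vars("nu", m_eq)
    lam = mb.add_vars("lam", m_ub, lb=0.0, ub=M_dual)

    xi: dict[int, int] = {}
    for r in range(m_ub):
        k = inner.row_kcol[r]
        if k >= 0:
            xi[r] = mb.mark_product(z[k], lam[r], M=M_dual)

    # outer objective: target flux of the inner response
    mb.set_objective([(x[i], inner.f[i]) for i in range(n_x)], sense="max")

    mb.add_constr([(zi, 1.0) for zi in z], lb=n_kn - K, name="budget")
    from .pessimistic import add_no_good_cuts

    add_no_good_cuts(mb, z, inner.knockable, exclude)

    # primal feasibility: A x = 0, B x - Bz z <= b0
    for q in range(m_eq):
        mb.add_constr([(x[i], inner.A[q, i]) for i in range(n_x)], lb=0.0, ub=0.0,
                      name=f"eq[{q}]")
    for r in range(m_ub):
        coeffs = [(x[i], inner.B[r, i]) for i in range(n_x)]
        k = inner.row_kcol[r]
        if k >= 0:
            coeffs.append((z[k], -inner.Bz[r, k]))
        mb.add_constr(coeffs, ub=inner.b0[r], name=f"ub[{inner.row_names[r]}]")

    # dual feasibility: A^T nu + B^T lam = c_in
    for i in range(n_x):
        coeffs = [(nu[q], inner.A[q, i]) for q in range(m_eq)]
        coeffs += [(lam[r], inner.B[r, i]) for r in range(m_ub)]
        mb.add_constr(coeffs, lb=inner.c_in[i], ub=inner.c_in[i],
                      name=f"dual[{inner.x_names[i]}]")

    # strong duality: c_in^T x = b0^T lam + sum_r Bz_r xi_r
    sd = [(x[i], inner.c_in[i]) for i in range(n_x)]
    sd += [(lam[r], -inner.b0[r]) for r in range(m_ub)]
    sd += [(xi[r], -inner.Bz[r, inner.row_kcol[r]]) for r in xi]
    mb.add_constr(sd, lb=0.0, ub=0.0, name="strong_duality")

    linearize_products(mb, BigMConfig(M_dual=M_dual))
    return mb, {"z": z, "x": x, "lam": lam, "xi": xi, "nu": nu}


def _solve_optimistic(
    model: MetabolicModel,
    K: int,
    kind: str,
    w: WildTypeReference | None,
    bigm: BigMConfig | None,
    mip_rel_gap: float,
    time_limit: float | None,
    exclude=(),
) -> DesignResult:
    if not 0 <= K <= len(model.knockable_ids()):
        raise ValueError(f"K={K} outside [0, {len(model.knockable_ids())}]")
    bigm = bigm or BigMConfig()
    inner = build_inner(model, kind, w)
    method = "room" if kind == "room" else "optknock"

    from .pessimistic import _solve_with_escalation

    def audit(res, idx):
        if not idx["xi"]:
            return 0.0
        return max(abs(float(res.x[idx["lam"][r]])) for r in idx["xi"])

    res, idx, stats = _solve_with_escalation(
        lambda M: _assemble_optimistic(inner, K, M, bigm, exclude=exclude),
        audit, bigm, mip_rel_gap, time_limit,
    )
    if res is None:
        status = stats.get("status", "error")
        return DesignResult(
            design=KnockoutDesign.empty(K),
            objective=float("nan"),
            method=method,
            status=status if status == "infeasible" else f"error:{status}",
            solver_stats=stats,
        )
    knocked = frozenset(
        rid for k, rid in enumerate(inner.knockable) if res.x[idx["z"][k]] < 0.5
    )
    x_val = np.array([res.x[i] for i in idx["x"]])
    lam_val = np.array([res.x[i] for i in idx["lam"]])
    xi_val = {r: float(res.x[i]) for r, i in idx["xi"].items()}
    primal_obj = float(inner.c_in @ x_val)
    dual_obj = float(inner.b0 @ lam_val) + sum(
        inner.Bz[r, inner.row_kcol[r]] * v for r, v in xi_val.items()
    )
    design = KnockoutDesign(knocked, K)
    stats.update({
        "inner_primal_objective": inner.natural_value(primal_obj),
        "inner_dual_objective": inner.natural_value(dual_obj),
        "strong_duality_gap": abs(primal_obj - dual_obj),
        "milp_bound": float(res.objective),
    })
    # certify the cooperative value of the selected design with the exact
    # lexicographic two-stage LP (inner optimum, then max target flux)
    from .evaluate import InfeasibleDesignError, epsilon_extreme_flux

    try:
        ev = epsilon_extreme_flux(inner.model, design, kind, 0.0, w, sense="max")
        objective = ev.best_flux
        stats["certified"] = True
    except InfeasibleDesignError:
        objective = float(res.objective)
        stats["certified"] = False
    return DesignResult(
        design=design,
        objective=objective,
        method=method,
        status="optimal",
        solver_stats=stats,
    )


def solve_optknock(
    model: MetabolicModel,
    K: int,
    bigm: BigMConfig | None = None,
    mip_rel_gap: float = 1e-6,
    time_limit: float | None = None,
    exclude=(),
) -> DesignResult:
    """Cooperative design under the biomass-maximizing response model."""
    return _solve_optimistic(model, K, "biomass", None, bigm, mip_rel_gap, time_limit, exclude)


def solve_room_design(
    model: MetabolicModel,
    K: int,
    w: WildTypeReference,
    bigm: BigMConfig | None = None,
    mip_rel_gap: float = 1e-6,
    time_limit: float | None = None,
    exclude=(),
) -> DesignResult:
    """Cooperative design under the minimal-flux-change response model."""
    return _solve_optimistic(model, K, "room", w, bigm, mip_rel_gap, time_limit, exclude)


def enumerate_alternate_designs(solve, tol: float = 1e-6, max_designs: int = 10):
    """No-good-cut loop: all knockout sets whose objective ties the optimum.

    ``solve(exclude)`` must run one of the design MILPs with the given
    knockout sets excluded (e.g. ``lambda ex: solve_optknock(m, 2,
    exclude=ex)``).  Re-solves with exact-set exclusion cuts until the
    objective drops below the first optimum by more than ``tol``.
    """
    results = []
    excluded: list[frozenset] = []
    best = None
    while len(results) < max_designs:
        res = solve(tuple(excluded))
        if res.status != "optimal":
            break
        if best is None:
            best = res.objective
        elif res.objective < best - tol:
            break
        results.append(res)
        excluded.append(res.design.knocked)
    return results
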