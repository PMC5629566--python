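"""Pessimistic bi-level knockout design as single-level MILPs.

The pessimistic program picks the knockout vector ``z`` maximizing the
WORST-case target flux over all inner responses whose inner objective lies
within a multiplicative epsilon band of optimal.  With the inner model in
canonical form (see :mod:`pessiknock.inner`) the reduction is mechanical and
identical for both inner models:

1.  The inner LP ``max c_in^T x  s.t.  A x = 0, B x <= b0 + Bz z`` is
    replaced by its dual; by weak duality any dual-feasible ``(nu, lam)``
    over-estimates the inner optimum, so the adversary minimizing the target
    flux may also minimize over dual-feasible points and drives the band
    ``c_in^T x >= kappa * (b0 + Bz z)^T lam`` exactly to the true band.
    The result is a single adversary LP over ``(x, nu, lam)``.
2.  That adversary LP is dualized once more (variables ``gamma, beta, pi,
    t``), turning max-min into max-max, i.e. one maximization over ``z`` and
    the second-level duals jointly.
3.  A feasibility witness ``x_hat`` (the ``s``/``r`` block) keeps designs
    whose inner problem is infeasible out of the feasible region — without
    it the dual of an infeasible adversary problem is unbounded and the MILP
    could report arbitrary values.
4.  The bilinear ``binary x continuous`` products (``z * lam`` in the
    objective, ``z * t`` in the band-dual rows) are linearized exactly with
    the big-M construction; a post-solve activity audit escalates M when any
    continuous factor approaches its bound.

The optimistic baselines reuse steps 1 and 4 only (strong duality once).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import WildTypeReference
from .inner import InnerProblem, build_inner
from .model import KnockoutDesign, MetabolicModel
from .results import DesignResult
from .solver import MipBuilder, SolveResult, solve_lp


@dataclass
class BigMConfig:
    """Big-M magnitudes for product linearization plus the audit settings.

    ``M_flux`` bounds flux-type factors and defaults to the largest bound
    magnitude in the model; ``M_dual`` bounds dual-variable factors (LP duals
    have no a-priori bound, hence the post-solve activity audit: if any
    factor lands within ``audit_margin`` of its M the run is deemed invalid
    and M is escalated).
    """

    M_flux: float | None = None
    M_dual: float = 1e4
    audit_margin: float = 0.05
    max_escalations: int = 2
    #: wall-clock cap per escalated re-solve; if an escalated program times
    #: out, the last successful (certified) solve is kept and flagged
    escalation_time_limit: float = 10.0

    def flux_bound(self, model: MetabolicModel) -> float:
        if self.M_flux is not None:
            return self.M_flux
        return max(
            max(abs(r.lower_bound), abs(r.upper_bound)) for r in model.reactions
        )


def linearize_products(builder: MipBuilder, config: BigMConfig) -> MipBuilder:
    """Replace every registered product ``xi = z * x`` by its big-M rows.

    For each product the four inequalities ``xi <= M z``, ``xi >= -M z``,
    ``xi <= x + M (1 - z)`` and ``xi >= x - M (1 - z)`` are appended; the
    relaxation is exact whenever ``|x| <= M`` at the optimum, which the
    caller's audit verifies.
    """
    for prod in builder.pending_products:
        M = prod.M if prod.M is not None else config.M_dual
        if not np.isfinite(M) or M <= 0:
            raise ValueError(
                f"product {builder.names[prod.xi]}: no finite big-M bound configured"
            )
        builder.add_constr([(prod.xi, 1.0), (prod.z, -M)], ub=0.0)
        builder.add_constr([(prod.xi, 1.0), (prod.z, M)], lb=0.0)
        builder.add_constr([(prod.xi, 1.0), (prod.x, -1.0), (prod.z, M)], ub=M)
        builder.add_constr([(prod.xi, 1.0), (prod.x, -1.0), (prod.z, -M)], lb=-M)
    builder.pending_products = []
    return builder


def _solve_with_escalation(assemble, audit, bigm: BigMConfig, mip_rel_gap, time_limit):
    """Big-M activity audit with bounded escalation.

    ``assemble(M)`` builds the MILP, ``audit(res, idx)`` returns the largest
    |continuous factor| among the linearized products.  A factor within
    ``audit_margin`` of M invalidates the relaxation, so M is escalated and
    the program re-solved (under a wall-clock cap: ill-conditioned escalated
    programs may branch endlessly, in which case the last successful solve is
    kept and flagged).  Returns ``(res, idx, stats)``; ``res`` is None when
    no attempt produced a solution.
    """
    M = bigm.M_dual
    last = None
    res = None
    for attempt in range(bigm.max_escalations + 1):
        tl = time_limit
        if attempt > 0:
            tl = bigm.escalation_time_limit if tl is None else min(tl, bigm.escalation_time_limit)
        mb, idx = assemble(M)
        res = mb.solve(mip_rel_gap=mip_rel_gap, time_limit=tl)
        if res.status == "optimal":
            peak = audit(res, idx)
            ok = peak <= (1 - bigm.audit_margin) * M
            last = (res, idx, {
                "big_M_dual": M, "bigM_escalations": attempt,
                "bigM_peak_factor": peak, "bigM_audit_ok": ok,
                "mip_gap": res.mip_gap,
            })
            if ok:
                break
        elif last is not None:
            break  # escalated re-solve failed; keep the flagged previous result
        elif res.status not in ("infeasible", "error") or attempt >= bigm.max_escalations:
            return None, None, {"big_M_dual": M, "status": res.status}
        # a too-small dual cap can render the dual block infeasible (and
        # near-infeasibility often surfaces as solver numerical trouble)
        M *= 10.0
    if last is None:
        return None, None, {"big_M_dual": M, "status": res.status}
    return last


# ---------------------------------------------------------------------------
# inner dual (strong-duality block of the minimal-flux-change model)


@dataclass
class RoomInnerDual:
    """Dual LP of the minimal-flux-change inner problem for a fixed design.

    Maximizes the dual objective ``-b(z)^T lam`` subject to dual feasibility
    ``A^T nu + B^T lam = c_in`` with ``lam >= 0``; by strong duality its
    optimum equals the inner primal optimum ``sum_j y_j*``.  Row groups of
    ``lam`` recover the named duals: bound rows (mu_min/mu_max), the
    viability threshold (mu_biom), the flux-change rows (mu_min2/mu_max2)
    and the ``y <= 1`` bounds (a).  The dual of the fixed-uptake equality is
    the net ``mu_min - mu_max`` on the uptake reaction's bound-row pair.
    """

    inner: InnerProblem
    design: KnockoutDesign

    def solve(self) -> SolveResult:
        inner = self.inner
        b = inner.b_of(self.design)
        m_eq, m_ub = inner.A.shape[0], inner.B.shape[0]
        # variables: nu (free), lam (>= 0)
        c = np.concatenate([np.zeros(m_eq), -b])
        A_eq = np.hstack([inner.A.T, inner.B.T])
        res = solve_lp(
            c,
            A_eq=A_eq,
            b_eq=inner.c_in,
            bounds=[(None, None)] * m_eq + [(0.0, None)] * m_ub,
            sense="max",
        )
        if res.status == "unbounded":
            return SolveResult(status="infeasible-design", objective=None, x=None)
        return res

    def named_duals(self, res: SolveResult) -> dict[str, dict[str, float]]:
        m_eq = self.inner.A.shape[0]
        lam = res.x[m_eq:]
        groups: dict[str, dict[str, float]] = {}
        prefix_map = {
            "ub": "mu_max", "lb": "mu_min", "chg_up": "mu_max2",
            "chg_dn": "mu_min2", "y_ub": "a",
        }
        for r, name in enumerate(self.inner.row_names):
            if name == "biomass_min":
                groups.setdefault("mu_biom", {})[""] = float(lam[r])
                continue
            prefix, _, rid = name.partition("[")
            key = prefix_map.get(prefix)
            if key:
                groups.setdefault(key, {})[rid.rstrip("]")] = float(lam[r])
        return groups


def build_room_inner_dual(
    model: MetabolicModel, w: WildTypeReference, design: KnockoutDesign
) -> RoomInnerDual:
    """Dual LP of the inner minimal-flux-change problem for a fixed design."""
    design.validate_against(model)
    return RoomInnerDual(inner=build_inner(model, "room", w), design=design)


# ---------------------------------------------------------------------------
# single-level pessimistic MILP


def add_no_good_cuts(mb: MipBuilder, z: list[int], knockable: list[str], exclude) -> None:
    """Exclude exact knockout sets: any feasible z must differ in >= 1 position."""
    for knocked in exclude:
        coeffs = []
        rhs = 1 - sum(1 for rid in knockable if rid not in knocked)
        for k, rid in enumerate(knockable):
            coeffs.append((z[k], 1.0 if rid in knocked else -1.0))
        mb.add_constr(coeffs, lb=rhs, name="no_good")


def _assemble_pessimistic(
    inner: InnerProblem, K: int, epsilon: float, M_dual: float, bigm: BigMConfig,
    exclude=(),
) -> tuple[MipBuilder, dict]:
    model = inner.model
    kappa = inner.kappa(epsilon)
    n_x = inner.n_x
    m_eq, m_ub = inner.A.shape[0], inner.B.shape[0]
    n_kn = len(inner.knockable)
    M_flux = bigm.flux_bound(model)

    mb = MipBuilder()
    z = mb.add_vars("z", n_kn, lb=0, ub=1, integer=True)
    gamma = mb.add_vars("gamma", m_eq)
    beta = mb.add_vars("beta", m_ub, lb=0.0, ub=M_dual)
    pi = mb.add_vars("pi", n_x)
    t = mb.add_var("t", lb=0.0, ub=M_dual)
    xhat = mb.add_vars("xhat", n_x, lb=-M_flux, ub=M_flux)

    # products: xi_r = beta_r * z_{kcol(r)} for z-scaled rows; tau_k = t * z_k
    xi: dict[int, int] = {}
    for r in range(m_ub):
        k = inner.row_kcol[r]
        if k >= 0:
            xi[r] = mb.mark_product(z[k], beta[r], M=M_dual)
    tau = [mb.mark_product(z[k], t, M=M_dual) for k in range(n_kn)]

    # objective: max  -b0^T beta - sum_r Bz_r xi_r - c_in^T pi
    obj = [(beta[r], -inner.b0[r]) for r in range(m_ub)]
    obj += [(xi[r], -inner.Bz[r, inner.row_kcol[r]]) for r in xi]
    obj += [(pi[i], -inner.c_in[i]) for i in range(n_x)]
    mb.set_objective(obj, sense="max")

    # knockout budget: sum z >= n_kn - K
    mb.add_constr([(zi, 1.0) for zi in z], lb=n_kn - K, name="budget")
    add_no_good_cuts(mb, z, inner.knockable, exclude)

    # dual feasibility of the adversary LP, x-block:
    #   A^T gamma + B^T beta - c_in t = -f
    for i in range(n_x):
        coeffs = [(gamma[q], inner.A[q, i]) for q in range(m_eq)]
        coeffs += [(beta[r], inner.B[r, i]) for r in range(m_ub)]
        coeffs.append((t, -inner.c_in[i]))
        mb.add_constr(coeffs, lb=-inner.f[i], ub=-inner.f[i], name=f"dx[{inner.x_names[i]}]")

    # nu-block: A pi = 0
    for q in range(m_eq):
        mb.add_constr([(pi[i], inner.A[q, i]) for i in range(n_x)], lb=0.0, ub=0.0,
                      name=f"dnu[{q}]")

    # lam-block: B pi + kappa b0 t + kappa Bz_r tau >= 0
    for r in range(m_ub):
        coeffs = [(pi[i], inner.B[r, i]) for i in range(n_x)]
        coeffs.append((t, kappa * inner.b0[r]))
        k = inner.row_kcol[r]
        if k >= 0:
            coeffs.append((tau[k], kappa * inner.Bz[r, k]))
        mb.add_constr(coeffs, lb=0.0, name=f"dlam[{inner.row_names[r]}]")

    # feasibility witness: A xhat = 0, B xhat - Bz z <= b0
    for q in range(m_eq):
        mb.add_constr([(xhat[i], inner.A[q, i]) for i in range(n_x)], lb=0.0, ub=0.0,
                      name=f"wit_eq[{q}]")
    for r in range(m_ub):
        coeffs = [(xhat[i], inner.B[r, i]) for i in range(n_x)]
        k = inner.row_kcol[r]
        if k >= 0:
            coeffs.append((z[k], -inner.Bz[r, k]))
        mb.add_constr(coeffs, ub=inner.b0[r], name=f"wit_ub[{inner.row_names[r]}]")

    linearize_products(mb, BigMConfig(M_dual=M_dual))
    idx = {"z": z, "beta": beta, "t": t, "xi": xi, "tau": tau}
    return mb, idx


def _solve_pessimistic(
    model: MetabolicModel,
    K: int,
    epsilon: float,
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
    method = "p_room" if kind == "room" else "p_optknock"

    def audit(res, idx):
        worst = abs(float(res.x[idx["t"]]))
        for r in idx["xi"]:  # the continuous factor of xi_r is beta_r
            worst = max(worst, abs(float(res.x[idx["beta"][r]])))
        return worst

    res, idx, stats = _solve_with_escalation(
        lambda M: _assemble_pessimistic(inner, K, epsilon, M, bigm, exclude=exclude),
        audit, bigm, mip_rel_gap, time_limit,
    )
    if res is None:
        status = stats.get("status", "error")
        return DesignResult(
            design=KnockoutDesign.empty(K),
            objective=float("nan"),
            method=method,
            epsilon=epsilon,
            status=status if status == "infeasible" else f"error:{status}",
            solver_stats=stats,
        )
    knocked = frozenset(
        rid for k, rid in enumerate(inner.knockable) if res.x[idx["z"][k]] < 0.5
    )
    design = KnockoutDesign(knocked, K)
    stats["milp_bound"] = float(res.objective)
    # the MILP selects the design; certify its guaranteed worst-case flux
    # exactly with the two-stage LP (immune to big-M round-off)
    from .evaluate import InfeasibleDesignError, epsilon_extreme_flux

    try:
        ev = epsilon_extreme_flux(inner.model, design, kind, epsilon, w, sense="min")
        objective = ev.worst_flux
        stats["certified"] = True
    except InfeasibleDesignError:
        objective = float(res.objective)
        stats["certified"] = False
    return DesignResult(
        design=design,
        objective=objective,
        method=method,
        epsilon=epsilon,
        status="optimal",
        solver_stats=stats,
    )


def solve_p_room(
    model: MetabolicModel,
    K: int,
    epsilon: float,
    w: WildTypeReference,
    bigm: BigMConfig | None = None,
    mip_rel_gap: float = 1e-6,
    time_limit: float | None = None,
    exclude=(),
) -> DesignResult:
    """Robust design under the minimal-flux-change response model.

    Maximizes the worst-case target flux over all responses ``(v, y)`` whose
    change count satisfies ``sum y <= (1 + epsilon) sum y*``; the reported
    objective is the guaranteed production rate.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return _solve_pessimistic(model, K, epsilon, "room", w, bigm, mip_rel_gap,
                              time_limit, exclude)


def solve_p_optknock(
    model: MetabolicModel,
    K: int,
    epsilon: float,
    bigm: BigMConfig | None = None,
    mip_rel_gap: float = 1e-6,
    time_limit: float | None = None,
    exclude=(),
) -> DesignResult:
    """Robust design under the biomass-maximizing response model.

    Maximizes the worst-case target flux over all responses with
    ``v_biom >= (1 - epsilon) * phi*(z)`` (and above the viability
    threshold).  At ``epsilon = 0`` this is the fully pessimistic design over
    the biomass-optimal face.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must be in [0, 1] for the biomass inner model")
    return _solve_pessimistic(model, K, epsilon, "biomass", None, bigm, mip_rel_gap,
                              time_limit, exclude)
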