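"""Worst-/best-case evaluation of fixed knockout designs, and the brute-force
pessimistic oracle.

Given a fixed design, ``inner_optimum`` solves the inner LP (max biomass, or
min total flux change for the ROOM-type model) and ``epsilon_extreme_flux``
then optimizes the target flux over the epsilon-approximation band around
that optimum: every inner response whose objective is within a multiplicative
(1 +/- epsilon) factor of optimal.  ``sense=min`` is the pessimistic
(guaranteed) production rate, ``sense=max`` the optimistic one — the same
procedure evaluates designs produced by any method.

``pessimistic_enumeration_oracle`` scores every feasible design of size <= K
by its worst-case flux and returns the best; it is the independent referee
for the single-level MILP formulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .fba import WildTypeReference
from .inner import InnerProblem, build_inner
from .model import KnockoutDesign, MetabolicModel
from .results import DesignResult
from .solver import solve_lp

#: absolute slack added to the epsilon band so stage 2 cannot be spuriously
#: infeasible at epsilon = 0 due to LP round-off
BAND_SLACK = 1e-7


class InfeasibleDesignError(ValueError):
    """The inner problem has no feasible response under this design."""


class EnumerationBudgetError(RuntimeError):
    """The design space is too large for exhaustive enumeration."""


@dataclass
class EvaluationResult:
    """Extreme target fluxes of one design within the epsilon band."""

    design: KnockoutDesign
    inner_model: str
    epsilon: float
    worst_flux: float
    best_flux: float
    inner_optimum: float  # natural scale: sum y* (room) or max biomass


def _inner_optimum(inner: InnerProblem, design: KnockoutDesign) -> float:
    """Maximization-orientation inner optimum phi~ for a fixed design."""
    b = inner.b_of(design)
    res = solve_lp(
        inner.c_in,
        A_ub=inner.B,
        b_ub=b,
        A_eq=inner.A,
        b_eq=np.zeros(inner.A.shape[0]),
        sense="max",
    )
    if not res.optimal:
        raise InfeasibleDesignError(
            f"inner {inner.kind} problem is {res.status} for design {sorted(design.knocked)}"
        )
    return float(res.objective)


def inner_optimum(
    model: MetabolicModel,
    design: KnockoutDesign,
    inner_model: str,
    w: WildTypeReference | None = None,
) -> float:
    """Inner-LP optimum for a fixed design, on the model's natural scale."""
    design.validate_against(model)
    inner = build_inner(model, inner_model, w)
    return inner.natural_value(_inner_optimum(inner, design))


def _extreme_flux(
    inner: InnerProblem,
    design: KnockoutDesign,
    epsilon: float,
    sense: str,
    phi_tilde: float,
) -> float:
    """Stage 2: optimize the target flux inside the epsilon band."""
    b = inner.b_of(design)
    kappa = inner.kappa(epsilon)
    # band: c_in^T x >= kappa * phi~  ->  -c_in^T x <= -kappa * phi~ (+ slack)
    A_ub = np.vstack([inner.B, -inner.c_in])
    b_ub = np.concatenate([b, [-(kappa * phi_tilde) + BAND_SLACK]])
    res = solve_lp(
        inner.f,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=inner.A,
        b_eq=np.zeros(inner.A.shape[0]),
        sense=sense,
    )
    if not res.optimal:
        raise InfeasibleDesignError(f"epsilon-band stage unexpectedly {res.status}")
    return float(res.objective)


def epsilon_extreme_flux(
    model: MetabolicModel,
    design: KnockoutDesign,
    inner_model: str,
    epsilon: float,
    w: WildTypeReference | None = None,
    sense: str = "both",
) -> EvaluationResult:
    """Two-stage LP evaluation of a fixed design.

    Stage 1 computes the inner optimum; stage 2 minimizes and maximizes the
    target flux over all inner responses whose objective lies within the
    multiplicative epsilon band of that optimum (the viability threshold
    stays active throughout, so for the biomass model the effective
    constraint is ``v_biom >= max(biomass_min, (1 - eps) * phi*)``).
    ``sense`` is accepted for interface symmetry; both extremes are cheap
    and always reported.
    """
    if sense not in ("min", "max", "both"):
        raise ValueError(f"unknown sense {sense!r}")
    design.validate_against(model)
    inner = build_inner(model, inner_model, w)
    phi_tilde = _inner_optimum(inner, design)
    worst = _extreme_flux(inner, design, epsilon, "min", phi_tilde)
    best = _extreme_flux(inner, design, epsilon, "max", phi_tilde)
    return EvaluationResult(
        design=design,
        inner_model=inner_model,
        epsilon=epsilon,
        worst_flux=worst,
        best_flux=best,
        inner_optimum=inner.natural_value(phi_tilde),
    )


def iter_designs(model: MetabolicModel, K: int) -> "itertools.chain[KnockoutDesign]":
    """All designs of size <= K in (size, lexicographic) order."""
    ids = sorted(model.knockable_ids())
    return itertools.chain.from_iterable(
        (KnockoutDesign(frozenset(combo), K) for combo in itertools.combinations(ids, size))
        for size in range(K + 1)
    )


def pessimistic_enumeration_table(
    model: MetabolicModel,
    K: int,
    inner_model: str,
    epsilons: list[float],
    w: WildTypeReference | None = None,
    max_designs: int = 20000,
) -> dict[tuple[int, float], DesignResult]:
    """Brute-force pessimistic optima for every budget <= K and every epsilon.

    Each feasible design of size <= K is scored once per epsilon with the
    two-stage LP (the inner optimum is shared across epsilons); the returned
    mapping holds the argmax per (budget, epsilon).  Ties are broken
    deterministically: the first design in (size, lexicographic) enumeration
    order wins.
    """
    import math

    n = len(model.knockable_ids())
    total = sum(math.comb(n, k) for k in range(min(K, n) + 1))
    if total > max_designs:
        raise EnumerationBudgetError(
            f"{total} candidate designs exceed the enumeration budget {max_designs}"
        )
    inner = build_inner(model, inner_model, w)
    scored: list[tuple[KnockoutDesign, dict[float, float]]] = []
    for design in iter_designs(model, K):
        try:
            phi_tilde = _inner_optimum(inner, design)
            worsts = {
                eps: _extreme_flux(inner, design, eps, "min", phi_tilde) for eps in epsilons
            }
        except InfeasibleDesignError:
            continue
        scored.append((design, worsts))

    table: dict[tuple[int, float], DesignResult] = {}
    for budget in range(K + 1):
        for eps in epsilons:
            best: tuple[float, KnockoutDesign] | None = None
            for design, worsts in scored:
                if len(design.knocked) > budget:
                    continue
                if best is None or worsts[eps] > best[0] + 1e-9:
                    best = (worsts[eps], design)
            if best is None:
                table[(budget, eps)] = DesignResult(
                    design=KnockoutDesign.empty(budget),
                    objective=float("nan"),
                    method=f"oracle-{inner_model}",
                    epsilon=eps,
                    status="infeasible",
                )
            else:
                table[(budget, eps)] = DesignResult(
                    design=KnockoutDesign(best[1].knocked, budget),
                    objective=best[0],
                    method=f"oracle-{inner_model}",
                    epsilon=eps,
                    status="optimal",
                    solver_stats={"designs_scored": len(scored), "designs_total": total},
                )
    return table


def pessimistic_enumeration_oracle(
    model: MetabolicModel,
    K: int,
    inner_model: str,
    epsilon: float,
    w: WildTypeReference | None = None,
    max_designs: int = 20000,
) -> DesignResult:
    """Brute-force pessimistic design: argmax over designs of the worst-case flux.

    Every subset of knockable reactions of size <= K is scored with
    ``epsilon_extreme_flux(sense=min)``; infeasible designs are skipped.
    The independent referee for the single-level MILP formulations.
    """
    table = pessimistic_enumeration_table(
        model, K, inner_model, [epsilon], w, max_designs=max_designs
    )
    return table[(K, epsilon)]
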