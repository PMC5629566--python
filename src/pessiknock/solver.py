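"""Thin solver-backend contract over scipy's HiGHS interfaces.

All linear and mixed-integer programs in the package go through this module:
:func:`solve_lp` wraps ``scipy.optimize.linprog`` (returning primal values,
duals and a normalized status) and :class:`MipBuilder` assembles sparse
mixed-integer programs incrementally for ``scipy.optimize.milp``.  HiGHS is
deterministic and single-threaded here, which keeps every design and sweep
reproducible.
"""

from __future__ import annotations

import contextlib
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp


@contextlib.contextmanager
def _quiet_native_output():
    """Silence HiGHS' C-level stdout/stderr chatter during a solve."""
    try:
        sys.stdout.flush()
        sys.stderr.flush()
        saved = [os.dup(1), os.dup(2)]
    except (OSError, ValueError):  # non-standard streams: nothing to silence
        yield
        return
    devnull = os.open(os.devnull, os.O_WRONLY)

    def _flush_c_streams() -> None:
        try:
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:
            pass

    try:
        os.dup2(devnull, 1)
        os.dup2(devnull, 2)
        yield
    finally:
        _flush_c_streams()
        os.dup2(saved[0], 1)
        os.dup2(saved[1], 2)
        for fd in saved:
            os.close(fd)
        os.close(devnull)

#: scipy status codes -> package-wide status strings
_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "error"}

FEASIBILITY_TOL = 1e-6
DEFAULT_MIP_GAP = 1e-6


@dataclass
class SolveResult:
    """Status / objective / primal (and for LPs dual) values of one solve."""

    status: str
    objective: float | None
    x: np.ndarray | None
    dual_eq: np.ndarray | None = None
    dual_ub: np.ndarray | None = None
    mip_gap: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_lp(
    c,
    A_ub=None,
    b_ub=None,
    A_eq=None,
    b_eq=None,
    bounds=None,
    sense: str = "min",
) -> SolveResult:
    """Solve ``min/max c^T x`` subject to ``A_ub x <= b_ub``, ``A_eq x = b_eq``.

    ``bounds`` is a list of (lo, hi) pairs (None = unbounded side).  Returns
    primal values and the HiGHS duals of both constraint blocks.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds if bounds is not None else [(None, None)] * len(c),
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return SolveResult(status, None, None)
    return SolveResult(
        status="optimal",
        objective=sign * res.fun,
        x=res.x,
        dual_eq=None if A_eq is None else np.asarray(res.eqlin.marginals),
        dual_ub=None if A_ub is None else np.asarray(res.ineqlin.marginals),
    )


@dataclass
class _PendingProduct:
    """A bilinear binary x continuous product awaiting big-M linearization."""

    xi: int  # auxiliary product variable
    z: int  # binary factor
    x: int  # continuous factor
    M: float | None  # bound magnitude for the continuous factor


class MipBuilder:
    """Incremental sparse (MI)LP: variables, constraint rows, objective.

    Bilinear ``binary x continuous`` products are registered with
    :meth:`mark_product`; they must be linearized (``linearize_products`` in
    the pessimistic-design module) before :meth:`solve` will accept the
    program.  :meth:`write_lp` dumps the assembled program in CPLEX LP format
    for inspection.
    """

    def __init__(self) -> None:
        self.names: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[bool] = []
        self.obj: dict[int, float] = {}
        self.sense: str = "max"
        self.rows: list[list[tuple[int, float]]] = []
        self.row_lb: list[float] = []
        self.row_ub: list[float] = []
        self.row_names: list[str] = []
        self.pending_products: list[_PendingProduct] = []

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def add_var(self, name: str, lb=-np.inf, ub=np.inf, integer: bool = False) -> int:
        self.names.append(name)
        self.lb.append(float(lb))
        self.ub.append(float(ub))
        self.integer.append(integer)
        return len(self.names) - 1

    def add_vars(self, prefix: str, n: int, lb=-np.inf, ub=np.inf, integer: bool = False) -> list[int]:
        return [self.add_var(f"{prefix}_{k}", lb, ub, integer) for k in range(n)]

    def add_constr(
        self,
        coeffs: list[tuple[int, float]],
        lb: float = -np.inf,
        ub: float = np.inf,
        name: str = "",
    ) -> int:
        merged: dict[int, float] = {}
        for idx, coef in coeffs:
            if coef:
                merged[idx] = merged.get(idx, 0.0) + coef
        self.rows.append(sorted(merged.items()))
        self.row_lb.append(float(lb))
        self.row_ub.append(float(ub))
        self.row_names.append(name or f"c{len(self.rows)}")
        return len(self.rows) - 1

    def set_objective(self, coeffs: list[tuple[int, float]], sense: str = "max") -> None:
        self.obj = {i: c for i, c in coeffs if c}
        self.sense = sense

    def mark_product(self, z: int, x: int, M: float | None = None, name: str = "") -> int:
        """Register xi = z * x (z binary, x continuous); returns the xi index."""
        if not self.integer[z]:
            raise ValueError("first factor of a product must be a binary variable")
        xi = self.add_var(name or f"xi[{self.names[z]}*{self.names[x]}]")
        self.pending_products.append(_PendingProduct(xi, z, x, M))
        return xi

    # -- solving -----------------------------------------------------------
    def _matrix(self) -> sp.csr_matrix:
        data, ri, ci = [], [], []
        for r, row in enumerate(self.rows):
            for idx, coef in row:
                ri.append(r)
                ci.append(idx)
                data.append(coef)
        return sp.csr_matrix((data, (ri, ci)), shape=(len(self.rows), self.n_vars))

    def solve(self, mip_rel_gap: float = DEFAULT_MIP_GAP, time_limit: float | None = None) -> SolveResult:
        if self.pending_products:
            raise ValueError(
                f"{len(self.pending_products)} bilinear product(s) not yet linearized"
            )
        c = np.zeros(self.n_vars)
        for i, coef in self.obj.items():
            c[i] = coef
        sign = -1.0 if self.sense == "max" else 1.0
        constraints = LinearConstraint(self._matrix(), np.array(self.row_lb), np.array(self.row_ub))
        # tight integrality/feasibility tolerances: with big-M rows, HiGHS'
        # default 1e-6 integrality slack on a binary can leak M * 1e-6 into
        # an embedded strong-duality equality and corrupt the design choice
        options: dict = {
            "mip_rel_gap": mip_rel_gap,
            "mip_feasibility_tolerance": 1e-8,
            "primal_feasibility_tolerance": 1e-7,
            "dual_feasibility_tolerance": 1e-7,
        }
        if time_limit is not None:
            options["time_limit"] = time_limit
        import warnings

        with _quiet_native_output(), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Unrecognized options")
            res = milp(
                sign * c,
                constraints=constraints,
                integrality=np.array(self.integer, dtype=int),
                bounds=Bounds(np.array(self.lb), np.array(self.ub)),
                options=options,
            )
        status = _STATUS.get(res.status, "error")
        if res.x is None:
            return SolveResult(status, None, None)
        return SolveResult(
            status=status,
            objective=sign * res.fun,
            x=res.x,
            mip_gap=getattr(res, "mip_gap", None),
        )

    def value(self, result: SolveResult, idx: int) -> float:
        return float(result.x[idx])

    # -- LP-format dump ----------------------------------------------------
    def write_lp(self, path) -> None:
        def term(coef: float, name: str) -> str:
            return f"{'+' if coef >= 0 else '-'} {abs(coef):.12g} {name}"

        lines = ["Maximize" if self.sense == "max" else "Minimize", " obj: "
                 + " ".join(term(c, self.names[i]) for i, c in sorted(self.obj.items()))]
        lines.append("Subject To")
        for r, row in enumerate(self.rows):
            expr = " ".join(term(c, self.names[i]) for i, c in row)
            lo, hi = self.row_lb[r], self.row_ub[r]
            nm = self.row_names[r]
            if lo == hi:
                lines.append(f" {nm}: {expr} = {lo:.12g}")
            else:
                if np.isfinite(hi):
                    lines.append(f" {nm}_u: {expr} <= {hi:.12g}")
                if np.isfinite(lo):
                    lines.append(f" {nm}_l: {expr} >= {lo:.12g}")
        lines.append("Bounds")
        for i, name in enumerate(self.names):
            lo, hi = self.lb[i], self.ub[i]
            lo_s = "-inf" if not np.isfinite(lo) else f"{lo:.12g}"
            hi_s = "+inf" if not np.isfinite(hi) else f"{hi:.12g}"
            lines.append(f" {lo_s} <= {name} <= {hi_s}")
        ints = [self.names[i] for i in range(self.n_vars) if self.integer[i]]
        if ints:
            lines.append("Binaries" if all(self.lb[i] == 0 and self.ub[i] == 1
                                           for i in range(self.n_vars) if self.integer[i]) else "Generals")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
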