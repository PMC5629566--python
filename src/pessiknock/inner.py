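"""Matrix form of the inner (cell-response) problems shared by all designs.

Both inner models are expressed in one canonical shape over variables ``x``:

* ``biomass`` — FBA response, ``x = v``, maximize ``v_biom``;
* ``room`` — minimal-flux-change response, ``x = (v, y)`` with relaxed
  change indicators ``y_j in [0, 1]``, minimize ``sum_j y_j``.

Canonical form (maximization orientation; the minimized change count enters
as ``c_in = -1`` on the ``y`` block)::

    max  c_in^T x
    s.t. A x = 0                      (mass balance)
         B x <= b0 + Bz z             (bounds, viability threshold,
                                       flux-change rows, y bounds)

``z`` is the 0/1 knockout vector over the knockable reactions; it enters only
the right-hand side of the bound rows (``v_min z <= v <= v_max z``), which is
what makes every downstream dualization mechanical.  The fixed uptake is
folded into the bound rows as an equality pair.  The epsilon band on the
inner objective is uniformly ``c_in^T x >= kappa * phi``, where ``phi`` is the
optimal ``c_in^T x`` and ``kappa = 1 - eps`` (biomass) or ``1 + eps`` (room:
``sum y <= (1 + eps) sum y*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import WildTypeReference
from .model import KnockoutDesign, MetabolicModel

INNER_KINDS = ("biomass", "room")


@dataclass
class InnerProblem:
    model: MetabolicModel
    kind: str
    x_names: list[str]
    A: np.ndarray  # (m_eq, n_x)
    B: np.ndarray  # (m_ub, n_x)
    b0: np.ndarray  # (m_ub,)
    Bz: np.ndarray  # (m_ub, n_kn)
    c_in: np.ndarray  # inner objective, maximization orientation
    f: np.ndarray  # outer objective (target flux) over x
    knockable: list[str]
    row_names: list[str]
    #: row index -> knockable column whose z scales that row's rhs (or -1)
    row_kcol: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_x(self) -> int:
        return len(self.x_names)

    @property
    def n_reactions(self) -> int:
        return len(self.model.reactions)

    def z_vector(self, design: KnockoutDesign) -> np.ndarray:
        return np.array([0.0 if rid in design.knocked else 1.0 for rid in self.knockable])

    def b_of(self, design: KnockoutDesign) -> np.ndarray:
        return self.b0 + self.Bz @ self.z_vector(design)

    def kappa(self, epsilon: float) -> float:
        if epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.kind == "biomass":
            if epsilon > 1:
                raise ValueError("epsilon must be in [0, 1] for the biomass inner model")
            return 1.0 - epsilon
        return 1.0 + epsilon

    def natural_value(self, phi_tilde: float) -> float:
        """Map the maximization-orientation optimum to the model's natural scale."""
        return phi_tilde if self.kind == "biomass" else -phi_tilde

    def v_slice(self, x: np.ndarray) -> np.ndarray:
        return x[: self.n_reactions]


def build_inner(
    model: MetabolicModel,
    kind: str,
    w: WildTypeReference | None = None,
) -> InnerProblem:
    """Assemble the canonical matrices for one inner model."""
    if kind not in INNER_KINDS:
        raise ValueError(f"unknown inner model {kind!r}")
    if kind == "room" and w is None:
        raise ValueError("the room inner model requires a wild-type reference w")

    rids = model.reaction_ids()
    nJ = len(rids)
    knockable = model.knockable_ids()
    kcol = {rid: k for k, rid in enumerate(knockable)}
    S, _ = model.stoichiometric_matrix()
    biom_j = rids.index(model.biomass_reaction.id)
    chem_j = rids.index(model.target_reaction.id)

    n_x = nJ if kind == "biomass" else 2 * nJ
    x_names = [f"v[{rid}]" for rid in rids]
    if kind == "room":
        x_names += [f"y[{rid}]" for rid in rids]

    A = np.zeros((S.shape[0], n_x))
    A[:, :nJ] = S

    rows: list[np.ndarray] = []
    b0: list[float] = []
    bz: list[tuple[int, float]] = []  # (knockable column, coefficient) aligned with rows
    row_names: list[str] = []

    def add_row(coefs: np.ndarray, rhs: float, kc: tuple[int, float] | None, name: str) -> None:
        rows.append(coefs)
        if kc is None:
            b0.append(rhs)
            bz.append((-1, 0.0))
        else:
            b0.append(0.0)
            bz.append(kc)
        row_names.append(name)

    for j, rid in enumerate(rids):
        lo, hi = model.effective_bounds(rid)
        kc = kcol.get(rid)
        up = np.zeros(n_x)
        up[j] = 1.0
        add_row(up, hi, None if kc is None else (kc, hi), f"ub[{rid}]")
        dn = np.zeros(n_x)
        dn[j] = -1.0
        add_row(dn, -lo, None if kc is None else (kc, -lo), f"lb[{rid}]")

    thr = np.zeros(n_x)
    thr[biom_j] = -1.0
    add_row(thr, -model.biomass_min, None, "biomass_min")

    if kind == "room":
        wv = np.array([w.w[rid] for rid in rids])
        for j, rid in enumerate(rids):
            lo, hi = model.effective_bounds(rid)
            cu = np.zeros(n_x)
            cu[j] = 1.0
            cu[nJ + j] = -(hi - wv[j])  # v_j - (vmax - w) y_j <= w_j
            add_row(cu, wv[j], None, f"chg_up[{rid}]")
            cd = np.zeros(n_x)
            cd[j] = -1.0
            cd[nJ + j] = lo - wv[j]  # -v_j + (vmin - w) y_j <= -w_j
            add_row(cd, -wv[j], None, f"chg_dn[{rid}]")
        for j, rid in enumerate(rids):
            yu = np.zeros(n_x)
            yu[nJ + j] = 1.0
            add_row(yu, 1.0, None, f"y_ub[{rid}]")
            yl = np.zeros(n_x)
            yl[nJ + j] = -1.0
            add_row(yl, 0.0, None, f"y_lb[{rid}]")

    m_ub = len(rows)
    B = np.vstack(rows)
    Bz = np.zeros((m_ub, len(knockable)))
    row_kcol = np.full(m_ub, -1, dtype=int)
    for r, (kc, coef) in enumerate(bz):
        if kc >= 0:
            Bz[r, kc] = coef
            row_kcol[r] = kc

    c_in = np.zeros(n_x)
    if kind == "biomass":
        c_in[biom_j] = 1.0
    else:
        c_in[nJ:] = -1.0

    f = np.zeros(n_x)
    f[chem_j] = 1.0

    return InnerProblem(
        model=model,
        kind=kind,
        x_names=x_names,
        A=A,
        B=B,
        b0=np.array(b0),
        Bz=Bz,
        c_in=c_in,
        f=f,
        knockable=list(knockable),
        row_names=row_names,
        row_kcol=row_kcol,
    )
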