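"""Stoichiometric metabolic-model containers and I/O.

The central object is :class:`MetabolicModel`: an ordered list of metabolites
and reactions, a fixed substrate-uptake rate and a minimum biomass flux.  The
steady-state constraint ``S v = 0`` is enforced for every metabolite not
flagged external; flux bounds are in mmol/gDW/hr throughout.  Models are
stored in a small JSON dialect (one document with ``metabolites``,
``reactions``, ``roles`` and ``parameters`` keys) and can also be read from
SBML Level 3 / FBC files via cobrapy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

ROLES = ("internal", "uptake", "biomass", "target", "exchange")

#: reaction roles that may be marked knockable under the default policy
DEFAULT_KNOCKABLE_ROLES = frozenset({"internal"})


class ModelFormatError(ValueError):
    """The input file does not parse in the named format."""


class ModelConfigurationError(ValueError):
    """Required role designations (uptake/biomass/target) cannot be resolved."""


class ModelIntegrityError(ValueError):
    """Internally inconsistent model (e.g. stoichiometry names an unknown metabolite)."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.  Mass balance is enforced iff ``external`` is False."""

    id: str
    name: str = ""
    external: bool = False


@dataclass
class Reaction:
    """A reaction column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed).  Exchange-type pseudo reactions are single sided.  ``role`` is
    one of ``internal / uptake / biomass / target / exchange``; exactly one
    reaction each carries the uptake, biomass and target roles in a valid
    model.  Knockouts force the flux of a ``knockable`` reaction to zero.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 100.0
    knockable: bool = False
    role: str = "internal"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    uptake_rate: float
    biomass_min: float = 0.0

    # -- lookups -----------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reactions_with_role(self, role: str) -> list[Reaction]:
        return [r for r in self.reactions if r.role == role]

    def role_reaction(self, role: str) -> Reaction:
        found = self.reactions_with_role(role)
        if len(found) != 1:
            raise ModelConfigurationError(
                f"expected exactly one reaction with role {role!r}, found {len(found)}"
            )
        return found[0]

    @property
    def uptake_reaction(self) -> Reaction:
        return self.role_reaction("uptake")

    @property
    def biomass_reaction(self) -> Reaction:
        return self.role_reaction("biomass")

    @property
    def target_reaction(self) -> Reaction:
        return self.role_reaction("target")

    def knockable_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.knockable]

    # -- matrix view -------------------------------------------------------
    def balanced_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.external]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense S over balanced metabolites (rows) x reactions (columns)."""
        rows = self.balanced_metabolite_ids()
        index = {mid: i for i, mid in enumerate(rows)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                i = index.get(mid)
                if i is not None:
                    S[i, j] = coef
        return S, rows

    def effective_bounds(self, rid: str) -> tuple[float, float]:
        """Flux bounds with the fixed-uptake equality folded in."""
        rxn = self.reaction(rid)
        if rxn.role == "uptake":
            return (self.uptake_rate, self.uptake_rate)
        return (rxn.lower_bound, rxn.upper_bound)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            uptake_rate=self.uptake_rate,
            biomass_min=self.biomass_min,
        )


@dataclass(frozen=True)
class KnockoutDesign:
    """A set of knocked-out reaction ids with a knockout budget K.

    ``z_j = 0`` exactly for the knocked reactions; all designs must satisfy
    ``|knocked| <= budget`` and knock only knockable reactions.
    """

    knocked: frozenset[str]
    budget: int

    @classmethod
    def empty(cls, budget: int = 0) -> "KnockoutDesign":
        return cls(frozenset(), budget)

    @classmethod
    def of(cls, ids: Iterable[str], budget: int | None = None) -> "KnockoutDesign":
        s = frozenset(ids)
        return cls(s, len(s) if budget is None else budget)

    def validate_against(self, model: MetabolicModel) -> None:
        if len(self.knocked) > self.budget:
            raise ValueError(f"design knocks {len(self.knocked)} > budget {self.budget}")
        knockable = set(model.knockable_ids())
        bad = self.knocked - knockable
        if bad:
            raise ValueError(f"non-knockable reactions in design: {sorted(bad)}")

    def z(self, rid: str) -> int:
        return 0 if rid in self.knocked else 1


@dataclass
class FluxSolution:
    """One steady-state flux vector with its objective value and solve status."""

    v: dict[str, float]
    objective: float | None
    status: str  # optimal | infeasible | unbounded | error


# ---------------------------------------------------------------------------
# validation


def validate_model(
    model: MetabolicModel,
    knockable_roles: frozenset[str] = DEFAULT_KNOCKABLE_ROLES,
    check_feasibility: bool = True,
) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid).

    Structural checks cover id uniqueness, stoichiometry integrity, bound
    ordering, role designations and the knockability policy; when
    ``check_feasibility`` is set, the wild-type FBA problem is additionally
    solved and the achievable maximum biomass compared with ``biomass_min``.
    """
    violations: list[str] = []
    mids = model.metabolite_ids()
    if len(set(mids)) != len(mids):
        violations.append("duplicate metabolite ids")
    if any(not m.id for m in model.metabolites):
        violations.append("empty metabolite id")
    rids = model.reaction_ids()
    if len(set(rids)) != len(rids):
        violations.append("duplicate reaction ids")
    known = set(mids)
    for r in model.reactions:
        if not r.stoichiometry:
            violations.append(f"reaction {r.id}: empty stoichiometry")
        unknown = set(r.stoichiometry) - known
        if unknown:
            violations.append(f"reaction {r.id}: unknown metabolites {sorted(unknown)}")
        if r.lower_bound > r.upper_bound:
            violations.append(
                f"reaction {r.id}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
            )
        if r.role not in ROLES:
            violations.append(f"reaction {r.id}: unknown role {r.role!r}")
        if r.knockable and r.role not in knockable_roles:
            violations.append(f"reaction {r.id}: role {r.role!r} is not knockable by policy")
    for role in ("uptake", "biomass", "target"):
        n = len(model.reactions_with_role(role))
        if n != 1:
            violations.append(f"expected exactly one {role} reaction, found {n}")
    if model.biomass_min < 0:
        violations.append("biomass_min must be nonnegative")
    try:
        up = model.uptake_reaction
    except ModelConfigurationError:
        up = None
    if up is not None and not (up.lower_bound <= model.uptake_rate <= up.upper_bound):
        violations.append("uptake_rate outside the uptake reaction's bounds")

    if violations or not check_feasibility:
        return violations

    from .fba import solve_fba  # deferred to avoid an import cycle

    sol = solve_fba(model, model.biomass_reaction.id, sense="max", enforce_biomass_min=False)
    if sol.status != "optimal":
        violations.append(f"wild-type FBA is {sol.status}")
    elif sol.objective < model.biomass_min - 1e-6:
        violations.append(
            "biomass target exceeds achievable maximum "
            f"({model.biomass_min} > {sol.objective:.6g})"
        )
    return violations


# ---------------------------------------------------------------------------
# tabular (JSON) dialect


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "external": m.external} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "knockable": r.knockable,
                "role": r.role,
            }
            for r in model.reactions
        ],
        "roles": {
            role: [r.id for r in model.reactions_with_role(role)]
            for role in ("uptake", "biomass", "target")
        },
        "parameters": {"uptake_rate": model.uptake_rate, "biomass_min": model.biomass_min},
    }


def _model_from_dict(doc: Mapping) -> MetabolicModel:
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), bool(m.get("external", False)))
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 100.0)),
                knockable=bool(r.get("knockable", False)),
                role=r.get("role", "internal"),
            )
            for r in doc["reactions"]
        ]
        params = doc.get("parameters", {})
        model = MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            uptake_rate=float(params.get("uptake_rate", 0.0)),
            biomass_min=float(params.get("biomass_min", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed tabular model document: {exc}") from exc

    # the top-level roles block, when present, overrides per-reaction roles
    roles = doc.get("roles", {})
    for role, ids in roles.items():
        for rid in ids:
            try:
                model.reaction(rid).role = role
            except KeyError as exc:
                raise ModelConfigurationError(f"roles block names unknown reaction {rid!r}") from exc

    known = set(model.metabolite_ids())
    for r in model.reactions:
        unknown = set(r.stoichiometry) - known
        if unknown:
            raise ModelIntegrityError(
                f"reaction {r.id!r} references unknown metabolite(s) {sorted(unknown)}"
            )
    for role in ("uptake", "biomass", "target"):
        if len(model.reactions_with_role(role)) != 1:
            raise ModelConfigurationError(f"model must designate exactly one {role} reaction")
    return model


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as the internal JSON dialect (UTF-8)."""
    path = Path(path)
    text = json.dumps(_model_to_dict(model), indent=1, sort_keys=False)
    path.write_text(text + "\n", encoding="utf-8")


def load_model(
    path: str | Path,
    format: str = "tabular",
    roles: Mapping[str, str] | None = None,
    uptake_rate: float | None = None,
    biomass_min: float | None = None,
    knockable: Iterable[str] | None = None,
) -> MetabolicModel:
    """Load a model from the internal JSON dialect or from SBML L3/FBC.

    ``roles`` maps role name -> reaction id and overrides/supplies the
    uptake/biomass/target designations (required for SBML files unless the
    FBC objective identifies the biomass reaction and the uptake/target
    reactions are named).  ``knockable`` whitelists knockable reaction ids;
    for SBML input the default is all internal reactions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: not valid JSON (line {exc.lineno}): {exc.msg}") from exc
        model = _model_from_dict(doc)
    elif format == "sbml":
        model = _load_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")

    if roles:
        for role, rid in roles.items():
            try:
                model.reaction(rid).role = role
            except KeyError as exc:
                raise ModelConfigurationError(
                    f"role override names unknown reaction {rid!r}"
                ) from exc
    if knockable is not None:
        whitelist = set(knockable)
        for r in model.reactions:
            r.knockable = r.id in whitelist
    else:
        # conservative default policy: role-designated reactions are never knockable
        for r in model.reactions:
            if r.role not in DEFAULT_KNOCKABLE_ROLES:
                r.knockable = False
    if uptake_rate is not None:
        model.uptake_rate = uptake_rate
    if biomass_min is not None:
        model.biomass_min = biomass_min
    for role in ("uptake", "biomass", "target"):
        if len(model.reactions_with_role(role)) != 1:
            raise ModelConfigurationError(
                f"model must designate exactly one {role} reaction "
                "(supply a roles override for SBML input)"
            )
    if model.uptake_rate == 0.0:
        up = model.uptake_reaction
        if up.lower_bound == up.upper_bound:
            model.uptake_rate = up.lower_bound
    return model


def _load_sbml(path: Path) -> MetabolicModel:
    """Read an SBML Level 3 + FBC file through cobrapy.

    The FBC objective designates the biomass reaction; uptake/target roles
    must be supplied by the caller via role overrides.  Boundary metabolites
    are flagged external; every non-exchange reaction defaults to knockable
    per the conservative policy (overridable via the ``knockable`` argument
    of :func:`load_model`).
    """
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mix of CobraSBMLError/ValueError
        raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc

    mets = [Metabolite(m.id, m.name or "", False) for m in cm.metabolites]
    biomass_ids = {r.id for r in cm.reactions if r.objective_coefficient}
    rxns = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        if not stoich:
            continue
        if r.id in biomass_ids:
            role = "biomass"
        elif r.boundary:
            role = "exchange"
        else:
            role = "internal"
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                knockable=(role == "internal"),
                role=role,
            )
        )
    return MetabolicModel(metabolites=mets, reactions=rxns, uptake_rate=0.0, biomass_min=0.0)
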