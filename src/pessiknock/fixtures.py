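"""Self-contained toy metabolic networks for tests, demos and oracles.

The fixtures emulate the structural features that make knockout design
interesting on real networks: a fixed substrate uptake, a biomass reaction
with a viability threshold, and competing secretion routes for the target
metabolite that leave the inner (cell-response) problem with multiple
optimal flux distributions.

``toy7``
    Fixed 9-reaction network on metabolites A-D.  Substrate A enters at a
    fixed 10 mmol/gDW/hr; two routes make biomass precursor B (direct R1 and
    the split route R4 producing 0.5 B + 0.5 C); C can be recycled to B
    (R3), secreted as the target chemical (CHEM) or lost through an
    uncredited sink (R5).  The sink is what makes optimistic designs
    fragile: at the cooperative optimum C may leave via CHEM, in the worst
    case it leaves via R5.

``diamond``
    Minimal 4-metabolite diamond with two equivalent routes to the biomass
    precursor; useful for degenerate-optimum (non-unique FBA) checks.

``random``
    Seeded generator of small mass-balanced, FBA-feasible networks with the
    same ingredients (fixed uptake, threshold biomass, target + uncredited
    sink, random internal conversions, occasional reversible reactions).
"""

from __future__ import annotations

import numpy as np

from .model import KnockoutDesign, MetabolicModel, Metabolite, Reaction


class FixtureGenerationError(RuntimeError):
    """The random generator failed to produce a feasible network."""


def _toy7() -> MetabolicModel:
    B = (0.0, 100.0)
    mets = [Metabolite(m) for m in "ABCD"]
    rxns = [
        Reaction("UP", {"A": 1.0}, 10.0, 10.0, knockable=False, role="uptake"),
        Reaction("R1", {"A": -1.0, "B": 1.0}, *B, knockable=True),
        Reaction("R2", {"A": -1.0, "D": 1.0}, *B, knockable=True),
        Reaction("R3", {"C": -1.0, "B": 1.0}, *B, knockable=True),
        Reaction("R4", {"A": -1.0, "B": 0.5, "C": 0.5}, *B, knockable=True),
        Reaction("R5", {"C": -1.0}, *B, knockable=True),  # uncredited sink
        Reaction("WD", {"D": -1.0}, *B, knockable=False, role="exchange"),
        Reaction("BIOM", {"B": -1.0}, *B, knockable=False, role="biomass"),
        Reaction("CHEM", {"C": -1.0}, *B, knockable=False, role="target"),
    ]
    return MetabolicModel(mets, rxns, uptake_rate=10.0, biomass_min=1.0)


def _diamond() -> MetabolicModel:
    B = (0.0, 100.0)
    mets = [Metabolite(m) for m in ["A", "B", "C", "D"]]
    rxns = [
        Reaction("UP", {"A": 1.0}, 10.0, 10.0, knockable=False, role="uptake"),
        Reaction("AB", {"A": -1.0, "B": 1.0}, *B, knockable=True),
        Reaction("AC", {"A": -1.0, "C": 1.0}, *B, knockable=True),
        Reaction("BD", {"B": -1.0, "D": 1.0}, *B, knockable=True),
        Reaction("CD", {"C": -1.0, "D": 1.0}, *B, knockable=True),
        Reaction("BIOM", {"D": -1.0}, *B, knockable=False, role="biomass"),
        Reaction("CHEM", {"C": -1.0}, *B, knockable=False, role="target"),
    ]
    return MetabolicModel(mets, rxns, uptake_rate=10.0, biomass_min=1.0)


def _random(seed: int, params: dict) -> MetabolicModel:
    n_mets = int(params.get("n_metabolites", 5))
    n_internal = int(params.get("n_internal", 5))
    max_knockable = int(params.get("max_knockable", 8))
    uptake = float(params.get("uptake_rate", 10.0))
    biomass_min = float(params.get("biomass_min", 1.0))
    attempts = int(params.get("attempts", 25))
    coefs = (0.5, 1.0, 1.5, 2.0)

    from .fba import solve_fba  # deferred import (fba depends on model only)

    for attempt in range(attempts):
        rng = np.random.default_rng([seed, attempt])
        mids = [f"M{i}" for i in range(n_mets)]
        substrate, biomass_met, target_met = mids[0], mids[1], mids[2]
        B = (0.0, 100.0)
        rxns = [
            Reaction("UP", {substrate: 1.0}, uptake, uptake, knockable=False, role="uptake"),
            # guaranteed biomass route and a competing split route to the target
            Reaction("G1", {substrate: -1.0, biomass_met: 1.0}, *B, knockable=True),
            Reaction(
                "G2",
                {substrate: -1.0, biomass_met: float(rng.choice(coefs)) / 2,
                 target_met: float(rng.choice(coefs)) / 2},
                *B,
                knockable=True,
            ),
            Reaction("SINK", {target_met: -1.0}, *B, knockable=True),  # uncredited sink
        ]
        for k in range(n_internal):
            sub, prod = rng.choice(n_mets, size=2, replace=False)
            stoich = {mids[sub]: -float(rng.choice(coefs)), mids[prod]: float(rng.choice(coefs))}
            if rng.random() < 0.3:  # occasional second product
                extra = int(rng.integers(n_mets))
                if mids[extra] not in stoich:
                    stoich[mids[extra]] = float(rng.choice(coefs))
            lo = -100.0 if rng.random() < 0.2 else 0.0
            rxns.append(Reaction(f"X{k}", stoich, lo, 100.0, knockable=True))
        # cap the knockable set
        knockable = [r for r in rxns if r.knockable]
        for r in knockable[max_knockable:]:
            r.knockable = False
        rxns.append(Reaction("BIOM", {biomass_met: -1.0}, *B, knockable=False, role="biomass"))
        rxns.append(Reaction("CHEM", {target_met: -1.0}, *B, knockable=False, role="target"))
        model = MetabolicModel([Metabolite(m) for m in mids], rxns, uptake, biomass_min)
        sol = solve_fba(model, "BIOM", sense="max", enforce_biomass_min=False)
        if sol.status == "optimal" and sol.objective >= biomass_min + 1e-6:
            return model
    raise FixtureGenerationError(
        f"no feasible random network for seed {seed} in {attempts} attempts"
    )


def make_fixture(name: str, seed: int = 0, params: dict | None = None) -> MetabolicModel:
    """Build a named fixture network (``toy7``, ``diamond`` or ``random``).

    ``random`` fixtures are reproducible: the same seed (and params) always
    yields the identical model.
    """
    params = dict(params or {})
    if name == "toy7":
        return _toy7()
    if name == "diamond":
        return _diamond()
    if name == "random":
        return _random(seed, params)
    raise ValueError(f"unknown fixture {name!r} (expected toy7, diamond or random)")
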