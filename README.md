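# pessiknock

Robust reaction-knockout design for targeted biochemical overproduction on
stoichiometric metabolic models — cooperative (optimistic) and worst-case
(pessimistic) bi-level strain optimization, reduced to single-level MILPs by
LP strong duality.

## Who this is for

Metabolic engineers and constraint-based-modeling researchers who want
knockout strategies whose predicted overproduction survives the two
assumptions classical bi-level methods make silently: that the inner
cell-response model is faithful, and that among tied responses the cell
picks the one most favorable to the engineer.  When either fails, designs
from cooperative formulations can produce far less than promised — often
nothing.  The pessimistic formulations here return the *guaranteed*
production rate under the least favorable response within a tolerance band.

## The model

Fluxes `v` (mmol/gDW/hr) satisfy `S v = 0`, bounds `v_min ≤ v ≤ v_max`, a
fixed substrate uptake and a viability threshold `v_biom ≥ v_biomass_min`.
A design knocks out at most `K` reactions (`v_j_min z_j ≤ v_j ≤ v_j_max z_j`,
`z` binary).  Four design problems are solved:

| method | inner (cell) model | outer objective |
|---|---|---|
| `optknock` | max `v_biom` | max `v_chem`, cooperative |
| `room` | min Σ `y_j` (minimal flux change vs wild type `w`, LP relaxation) | max `v_chem`, cooperative |
| `p-optknock` | max `v_biom` | max over `z` of the **worst-case** `v_chem` over all responses with `v_biom ≥ (1−ε)·φ*(z)` |
| `p-room` | min Σ `y_j` | max over `z` of the worst-case `v_chem` over all responses with Σ`y ≤ (1+ε)·φ*(z)` |

`ε` widens the set of responses the cell may adopt (`ε = 0`: exactly the
inner-optimal face).  The pessimistic programs are three-level; they become
single-level MILPs by dualizing the inner LP, then dualizing the adversary's
LP, with big-M linearization of the binary×dual products and a feasibility
witness that excludes designs with no viable response.  A fixed design —
including one produced by a cooperative method — can be stress-tested with
the same ε-band evaluator, and an exhaustive enumeration oracle referees the
MILPs on small networks.  See `docs/methods.md` for the derivation and the
numerical safeguards.

## Worked example

The bundled `toy7` network takes up substrate A at a fixed 10 mmol/gDW/hr.
Biomass precursor B is made either directly (R1) or via a split route (R4:
A → 0.5 B + 0.5 C) whose co-product C is the target chemical; C can also be
recycled to B (R3) or lost through an uncredited sink (R5).

```
$ pessiknock fixture --name toy7 --out toy7.json
$ pessiknock design --method p-optknock --model toy7.json --K 3 --eps 0
{
 "method": "p_optknock",
 "knocked": ["R1", "R3", "R5"],
 "budget": 3,
 "objective": 4.9999999,
 ...
}
```

Knocking R1, R3 and R5 leaves R4 as the only biomass route: any growing
mutant *must* co-produce C, and with the sink gone C can only leave through
the target exchange — production is growth-coupled, guaranteed at 5
mmol/gDW/hr (half the uptake, by the 0.5 stoichiometry).  Compare the
cooperative design: OptKnock with `K = 2` knocks {R1, R3} and predicts the
same 5, but evaluating it pessimistically (`pessiknock evaluate --inner
biomass --eps 0`) yields `"worst_flux": 0.0` — at the biomass optimum the
cell may just as well dump all C into the sink.  Sweeping the tolerance
band:

```
$ pessiknock sweep --config cfg.json --out sweep.tsv   # p-optknock, K=3, eps 0/0.25/0.5
method      K  epsilon  objective  knocked   status
p-optknock  3  0.0      4.9999999  R1,R3,R5  optimal
p-optknock  3  0.25     3.7499999  R1,R3,R5  optimal
p-optknock  3  0.5      2.4999999  R1,R3,R5  optimal
```

The guarantee degrades gracefully as 5·(1−ε): if biomass may drop to
(1−ε)·optimum, the freed substrate is diverted away from the target in the
worst case — but never below 5·(1−ε), unlike the cooperative design whose
guarantee is already zero.

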