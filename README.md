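# gasferm

Design of thermodynamically feasible overall conversions of C1 gases
(CH₄, CO, CO₂) into precursor metabolites, with a ferric/ferrous electron
acceptor, plus a minimal flux-balance engine to test designed gas
compositions inside a metabolic network.

## Who this is for

Metabolic engineers and modelers exploring gas fermentation — e.g. anaerobic
methane oxidation (reverse methanogenesis) by *Methanosarcina*-like hosts —
who want to know, *before* committing to a pathway: which gas mixtures can
reach a target metabolite at all, how much external electron acceptor that
takes, and what the stoichiometric yield ceiling is.

## The model

A design is one net conversion with signed molar coefficients s (substrates
negative, products positive):

    s₁ CH₄ + s₂ CO₂ + s₃ CO + s_w H₂O + s_h H⁺ + s_p HPO₄²⁻ + s_n NH₄⁺
      + s_s H₂S + F Fe³⁺  →  (10/n_C) P + F Fe²⁺

for a target product P fixed at 10 C-mol. The designer solves the linear
program

    max |s_g|   subject to
    Σᵢ sᵢ·n_{e,i} = 0       for each element e ∈ {C,H,O,N,S,P,Fe}
    Σᵢ sᵢ·zᵢ     = 0        (charge)
    Σᵢ sᵢ·ΔG′f(i) ≤ 0       (overall transformed Gibbs energy, kcal)
    |sᵢ| ≤ B = 10,  gases and gated helpers substrate-only

where g is one chosen gas (or a co-product). Phosphate, ammonium and
sulfide are enabled only when the product contains P, N or S. The per-carbon
degree of reduction γ = (4n_C + n_H − 2n_O − 3n_N + 5n_P + 6n_S)/n_C
summarizes why acceptor demand differs between targets (pyruvate γ=3,
oxaloacetate γ=2, acetyl-CoA γ=4.04).

The FBA layer solves max c·v subject to S·v = 0 and bounds, with optional
flux-variability analysis and the same overall-ΔG constraint expressed over
exchange fluxes. A packaged ~28-reaction toy reverse-methanogenesis core
network carries the HdrA2B2C2 electron-bifurcation reaction
(2 F₄₂₀H₂ + Fdx_ox + CoM-S-S-CoB → 2 F₄₂₀ + Fdx²⁻ + HSCoM + HSCoB).

## Worked example

```python
from gasferm import DesignProblem, design_conversion

d = design_conversion(DesignProblem(target="pyr", objective="ch4", ferric=6.66))
print(d.rounded())
print(round(d.delta_g, 1))
```

prints

```
{'pyr': 3.333, 'fe3': -6.66, 'fe2': 6.66, 'ch4': -4.999, 'co2': -5.001,
 'h2o': 0.002, 'h': 9.993}
-87.5
```

read: 4.999 mol CH₄ and 5.001 mol CO₂ are co-utilized with 6.66 mol ferric
to make 3.333 mol pyruvate (10 C-mol); the conversion is exergonic by
87.5 kcal. At zero ferric the same target flips to CO-rich co-utilization
(`objective="co"` gives |s_CO| = 7.778). The same queries are available from
the shell:

```
gasferm design --target pyr --ferric 6.66 --maximize ch4 --json
gasferm scan --target oxa --ferric 0:10:0.5 --step 0.05 --out ternary.csv
gasferm ferric-limits --target gap
gasferm fba --model toy.json --ch4 1.833 --co 7.166 --ferric 4 --split ch3h4spt
```

`ferric-limits --target gap` reports a minimum of ≈3.4 mol ferric before any
gas mixture can reach glyceraldehyde-3-phosphate — no mixture is exergonic
without an electron sink.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-derives, from a fresh registry load and fresh LP solves: the
maximize-one-gas conversion coefficients for six targets at their fixed
ferric levels, the fixed-composition oxaloacetate yield, the per-carbon
degrees of reduction of the CoA thioesters, and the pyruvate ferric ceiling
found by bisection. Output is one JSON object keyed by target id.

## Scope notes

The packaged formation-energy table is a documented reconstruction (see
`docs/methods.md`); quantities that depend on the exact table are treated as
properties, not desk-value reproductions. Genome-scale model results are out
of scope: the SBML path is exercised on the packaged toy network only.
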