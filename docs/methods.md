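# Methods

## The conversion-design LP

One overall conversion is a vector of signed molar coefficients over a small
species set: the three gases, the target (fixed at 10 C-mol, i.e. 10/n_C
mol), water and protons (free sign), hydrogenphosphate / ammonium / hydrogen
sulfide (substrate-only, enabled only when the target contains P, N or S),
and an oxidized/reduced acceptor couple pinned at (−F, +F). Constraints:
element balances over C, H, O, N, S, P, Fe; charge balance; a coefficient
bound B on every |sᵢ|; and overall ΔG′ ≤ threshold. The objective maximizes
the coefficient magnitude of one named species. Solved with scipy's HiGHS
`linprog`; every returned solution is re-checked for element/charge residuals
below 1e−6 before it is reported.

Choices that matter:

* **Ammonium, not ammonia.** The nitrogen helper is NH₄⁺ (charge +1). With
  neutral NH₃ the published N-containing designs do not charge- or
  H-balance; with NH₄⁺ they balance exactly.
* **Coefficient bound B = 10.** Not arbitrary: the published max-CH₄ designs
  saturate either the ferric or the proton coefficient at exactly 10, and
  the pyruvate ferric ceiling (charge balance forces s_H⁺ = F + 10/3, so
  F ≤ 6.66) only emerges with this bound. Configurable per problem.
* **Tie-breaking.** Alternate optima differ only in helper coefficients; a
  secondary LP minimizes |s_H₂O| + |s_H⁺| at the pinned optimum so reported
  designs are deterministic.
* **Infeasibility is classified**: `balance` (no balanced design exists,
  e.g. pyruvate from CO alone — 10 mol CO carries 20 available electrons
  against the 30 pyruvate needs) vs `thermo` (balanced designs exist but
  none is exergonic at the threshold).
* **Fixed compositions carry a ±5·10⁻³ mol box.** Published compositions
  are printed to three decimals (1.833 = 11/6); exact equality makes the
  balance system inconsistent at the 1.5·10⁻³ level, so fixed uptakes are
  enforced within half-printed-precision boxes. The oxaloacetate
  composition then yields 2.503 vs the exact 2.49975.
* **Ternary scan semantics.** The feasible set at fixed ferric is a curve
  on the composition simplex, so exact grid-ratio feasibility is
  measure-zero. A grid point is flagged feasible when a design exists whose
  gas coefficients lie within half a grid step (0.25 mol at step 0.05) of
  the nominal composition.
* **Carbon ceilings.** `max_carbon_fraction` leaves the ferric level as a
  free LP variable in [0, B] (with s_ox + s_red = 0 enforced) instead of an
  outer grid scan; one exact solve, and it reproduces the known ceilings
  (CH₄ can supply at most 50.0% of pyruvate carbon; CO up to 91.7% of
  oxaloacetate carbon).
* **Ferric limits** use bisection at 0.01 mol tolerance on LP feasibility,
  bracketed by a 0.5-mol pre-scan over [0, B].

## The formation-energy table

Standard transformed Gibbs energies of formation at pH 7.0, 298.15 K
(kcal/mol) are packaged per species. They were constructed once, from the
derivation, and not adjusted afterwards:

1. standard aqueous-species ΔfG° values (CRC/Alberty compilations) for the
   gases, helpers, the iron couple, and the small acids (pyruvate −472.27,
   oxaloacetate −793.29, 2-oxoglutarate −793.41 kJ/mol, …);
2. a per-hydrogen Legendre transform to pH 7, ΔfG′° = ΔfG° + n_H·RT ln10·pH
   (+39.956 kJ per H), which makes ΔfG′(H⁺) ≡ 0;
3. sugar phosphates from the parent sugar plus a phosphate-ester increment
   (+13.8 kJ hydrolysis convention) and a monoanion correction;
4. the CoA thioesters from a combustion-energy estimate (≈ −113.6 kJ per
   available electron) anchored to the known thioester hydrolysis energies,
   with the acetyl/succinyl difference tied to the succinate–acetate gap.

Validation, computed by this package: the re-created balance-determined
published conversions land within ~2 kcal of the printed overall ΔG values
(pyruvate max-CO −41.0 vs −40; oxaloacetate max-CO −63.3 vs −65;
2-ketoglutarate max-CO −58.4 vs −57; pyruvate max-CH₄ −87.5 vs −87), and
the glyceraldehyde-3-phosphate minimum ferric comes out at 3.41 vs the
printed 3.04. Quantities that probe the table more finely — the max-CO
optima of the phosphorylated sugars, whose printed ΔG is −5 kcal, i.e.
near-threshold — are *not* reproduced coefficient-wise: under this table
four of them are thermodynamically infeasible at their printed ferric
levels (their minimum ferric shifts by ≲1 mol). The CoA-thioester absolute
energies carry an uncertainty of order ±50 kcal/mol; only signs and
balance-determined coefficients are claimed for those rows.

## Degree of reduction

γ = (4n_C + n_H − 2n_O − 3n_N + 5n_P + 6n_S)/n_C with ionic charge ignored —
available electrons against the references CO₂, H₂O, NH₃, H₃PO₄, H₂SO₄.
This weight set reproduces every tabulated target value; note the published
table truncates rather than rounds (PEP 8/3 → 2.66, GAP 11/3 → 3.66,
G6P 23/6 → 3.83), and `tabulated_degree_of_reduction` mirrors that.

## The toy core network

The packaged model is a cofactor-level fixture (~28 reactions) for
ferric-dependent methanotrophy, not a genome-scale claim: methane
activation (Mcr, AOM direction) and methyl transfer (Mtr); the stepwise
methyl-oxidation branch (Mer, Mtd, a Mch/Ftr/Fmd lump) reducing F₄₂₀ and
ferredoxin; the electron-bifurcating HdrA2B2C2 reaction exactly as drawn
(2 F₄₂₀H₂ + Fdx_ox + CoM-S-S-CoB → 2 F₄₂₀ + Fdx²⁻ + HSCoM + HSCoB, four
electrons split 2:2); reversible membrane HdrDE at methanophenazine; Rnf
(Fdx²⁻ → methanophenazine); ferric reduction at methanophenazine; Cdh/CODH
acetyl-CoA synthesis; acetate/ethanol/butanol branches; an ATP-synthase and
maintenance lump.

Two deliberate fixture choices:

* **Fpo is irreversible toward F₄₂₀ reduction.** F₄₂₀H₂ reoxidation must
  therefore pass through the bifurcation complex (or the alcohol branches),
  which realizes the electron-routing indispensability property: with
  HdrA2B2C2 knocked out, the methane-only acetyl-CoA yield is exactly zero.
* **The acetyl-CoA sink returns the CoA moiety** (accoa → coa), keeping the
  conserved CoA pool closed.

Exchange convention: uptake negative, secretion positive; fluxes are mol
per 10 C-mol of gas. With CH₄ and ferric both fixed at 10, electron
accounting (8 e⁻ per CH₄ and per acetyl unit, 1 per Fe³⁺) caps the
acetyl-CoA sink at (80−10)/8 = 8.75 — the engine reproduces this exactly,
and cobrapy/GLPK agrees on the same SBML file. Because the toy network's
only carbon sinks are acetyl-derived (γ ≥ 4), gas mixtures designed for
oxidized targets (e.g. oxaloacetate) should be applied with the CO₂
exchange left free; pinning all three gases over-reduces the network.

## What the synthetic world does and does not establish

`generate_compounds` samples formulas over C₁–C₆ H O N S P, charges −3..+1,
and ΔfG′ uniform on [−400, +50] kcal/mol — wide enough that seeded design
problems land on both sides of the feasibility threshold. The brute-force
oracle enumerates the free directions of the balance system (typically one)
on a grid and closes the rest by exact linear solve; LP/oracle agreement on
100 seeded problems checks the optimizer, not the chemistry. Planted
networks validate FBA/FVA against constructed-in optima. None of this
establishes anything about real metabolite energetics beyond the packaged
table's own derivation.

## Numerical conventions

LP solver HiGHS with default tolerances; element/charge residual guard
1e−6; reported coefficients rounded to 3 decimals, ΔG to 2; bisection
tolerance 0.01 mol; ternary step 0.05 and ferric grid {0, 0.5, …, 10} by
default. Units: kcal/mol throughout (1 kcal = 4.184 kJ at ingest).

## Known limitations

No ionic-strength/pH re-transformation; no uncertainty propagation on
ΔfG′; no pathway-level (reaction-by-reaction) design — only overall
stoichiometries; acceptor couples must share a formula and differ in charge
(multi-electron couples like trithionate/bisulfite are not modeled); the
toy network is a fixture whose numbers characterize the fixture, not the
organism.
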