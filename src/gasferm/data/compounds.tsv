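# gasferm packaged compound registry.
# Standard transformed Gibbs energies of formation (kcal/mol) at pH 7.0,
# 298.15 K, computed from standard aqueous-species formation energies with a
# per-hydrogen Legendre transform (+RT ln10 * 7 per H); the CoA thioesters
# are group-contribution-style estimates (see docs/methods.md).
id	name	formula	charge	roles	dg_f_prime_kcal_mol
ch4	methane (aq)	CH4	0	gas_substrate	29.9940
co	carbon monoxide (aq)	CO	0	gas_substrate	-28.6567
co2	carbon dioxide (aq)	CO2	0	gas_substrate	-92.2515
h2o	water	H2O	0	helper	-37.5901
h	proton	H	1	helper	0.0
hpo4	hydrogenphosphate	HPO4	-2	helper	-250.7610
nh4	ammonium	NH4	1	helper	19.2292
h2s	hydrogen sulfide (aq)	H2S	0	helper	12.4481
fe3	ferric iron	Fe	3	acceptor_oxidized	-1.1233
fe2	ferrous iron	Fe	2	acceptor_reduced	-18.8576
pyr	pyruvate	C3H3O3	-1	target_product	-84.2259
pep	phosphoenolpyruvate	C3H3O6P	-2	target_product	-282.0223
gap	glyceraldehyde 3-phosphate	C3H6O6P	-1	target_product	-256.4196
oxa	oxaloacetate	C4H2O5	-2	target_product	-170.5012
e4p	erythrose 4-phosphate	C4H8O7P	-1	target_product	-273.2552
r5p	ribose 5-phosphate	C5H10O8P	-1	target_product	-289.5029
2kg	2-ketoglutarate	C5H4O5	-2	target_product	-151.4304
g6p	glucose 6-phosphate	C6H12O9P	-1	target_product	-313.7404
aca	acetyl-CoA	C23H35O17N7P3S	-3	target_product	-497.1319
sca	succinyl-CoA	C25H36O19N7P3S	-4	target_product	-579.7084
ac	acetate	C2H3O2	-1	coproduct	-59.6176
etoh	ethanol (aq)	C2H6O	0	coproduct	13.8857
poh	1-propanol (aq)	C3H8O	0	coproduct	34.3786
btoh	1-butanol (aq)	C4H10O	0	coproduct	54.4263
ptoh	1-pentanol (aq)	C5H12O	0	coproduct	75.1625
htoh	1-hexanol (aq)	C6H14O	0	coproduct	95.9344
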