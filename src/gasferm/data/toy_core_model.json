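{
  "id": "toy_reverse_methanogenesis_core",
  "description": "Cofactor-level core network for ferric-dependent methanotrophy by a Methanosarcina-like host. Carriers: F420/F420H2, ferredoxin, methanophenazine, CoM/CoB and the heterodisulfide CoM-S-S-CoB. The HdrABC reaction is the cytosolic electron-bifurcating heterodisulfide reductase: electron pairs from reduced F420 are split between ferredoxin (low potential) and the heterodisulfide (high potential). F420 regeneration (Fpo) is modeled irreversibly toward F420H2, so reoxidation of F420H2 must pass through the bifurcation complex. Exchange convention: uptake negative, secretion positive. Fluxes are mol per 10 C-mol of gas fed. This network is a documented fixture, not a genome-scale reconstruction.",
  "objective": "DM_accoa",
  "metabolites": {
    "ch4": "c", "co": "c", "co2": "c", "fe3": "c", "fe2": "c",
    "h2o": "c", "h": "c", "ac": "c", "etoh": "c", "btoh": "c",
    "mcom": "c", "hscom": "c", "hscob": "c", "comssb": "c",
    "ch3h4spt": "c", "ch2h4spt": "c", "chh4spt": "c", "h4spt": "c",
    "f420": "c", "f420h2": "c", "fdxo": "c", "fdxr": "c",
    "mpho": "c", "mphr": "c", "accoa": "c", "coa": "c",
    "adp": "c", "atp": "c", "pi": "c", "pmf": "c"
  },
  "reactions": [
    {"id": "Mcr", "metabolites": {"ch4": -1, "comssb": -1, "mcom": 1, "hscob": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "methyl-coenzyme M reductase, methane activation (AOM direction)"},
    {"id": "Mtr", "metabolites": {"mcom": -1, "h4spt": -1, "ch3h4spt": 1, "hscom": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "methyl-H4SPT:CoM methyltransferase (AOM direction)"},
    {"id": "Mer", "metabolites": {"ch3h4spt": -1, "f420": -1, "ch2h4spt": 1, "f420h2": 1},
     "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "F420-dependent methylene-H4SPT reductase"},
    {"id": "Mtd", "metabolites": {"ch2h4spt": -1, "f420": -1, "chh4spt": 1, "f420h2": 1},
     "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "F420-dependent methylene-H4SPT dehydrogenase"},
    {"id": "FmdL", "metabolites": {"chh4spt": -1, "h2o": -1, "fdxo": -1,
                                    "co2": 1, "h4spt": 1, "fdxr": 1, "h": 1},
     "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "Mch/Ftr/Fmd lump: methenyl-H4SPT to CO2 with ferredoxin reduction"},
    {"id": "HdrABC", "metabolites": {"f420h2": -2, "fdxo": -1, "comssb": -1,
                                      "f420": 2, "fdxr": 1, "hscom": 1, "hscob": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "cytosolic electron-bifurcating heterodisulfide reductase HdrA2B2C2"},
    {"id": "HdrDE", "metabolites": {"hscom": -1, "hscob": -1, "mpho": -1,
                                     "comssb": 1, "mphr": 1},
     "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "membrane-bound heterodisulfide reductase at methanophenazine"},
    {"id": "Fpo", "metabolites": {"mphr": -1, "f420": -1, "f420h2": 1, "mpho": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "F420H2 dehydrogenase, modeled toward F420 reduction only"},
    {"id": "Frc", "metabolites": {"mphr": -1, "fe3": -2, "mpho": 1, "fe2": 2, "pmf": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "ferric reduction at methanophenazine / cytochrome sites"},
    {"id": "Rnf", "metabolites": {"fdxr": -1, "mpho": -1, "fdxo": 1, "mphr": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "Rnf complex: reduced ferredoxin to methanophenazine"},
    {"id": "CODH", "metabolites": {"co2": -1, "fdxr": -1, "h": -1,
                                    "co": 1, "fdxo": 1, "h2o": 1},
     "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "CO dehydrogenase (CO2 + Fdx2- <-> CO)"},
    {"id": "Cdh", "metabolites": {"ch3h4spt": -1, "co": -1, "coa": -1,
                                   "accoa": 1, "h4spt": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "acetyl-CoA synthase branch of Cdh"},
    {"id": "PtaAck", "metabolites": {"accoa": -1, "adp": -1, "pi": -1,
                                      "ac": 1, "atp": 1, "coa": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "phosphotransacetylase / acetate kinase lump"},
    {"id": "AdhE", "metabolites": {"accoa": -1, "f420h2": -2, "etoh": 1, "f420": 2, "coa": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "ethanol branch (acetyl-CoA + 2 [2H])"},
    {"id": "Bld", "metabolites": {"accoa": -2, "f420h2": -4, "btoh": 1, "h2o": 1,
                                   "f420": 4, "coa": 2},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "butanol branch (2 acetyl-CoA + 4 [2H])"},
    {"id": "ATPS", "metabolites": {"pmf": -1, "adp": -1, "pi": -1, "atp": 1, "h2o": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "ATP synthase lump driven by the ion-motive force"},
    {"id": "ATPM", "metabolites": {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "non-growth maintenance / ATP drain"},
    {"id": "PMFd", "metabolites": {"pmf": -1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "dissipation of excess ion-motive force"},
    {"id": "DM_accoa", "metabolites": {"accoa": -1, "coa": 1},
     "lower_bound": 0, "upper_bound": 1000,
     "annotation": "acetyl-CoA sink (objective); returns the CoA moiety"},
    {"id": "EX_ch4", "metabolites": {"ch4": -1}, "lower_bound": -10, "upper_bound": 0,
     "annotation": "exchange: ch4"},
    {"id": "EX_co", "metabolites": {"co": -1}, "lower_bound": -10, "upper_bound": 0,
     "annotation": "exchange: co"},
    {"id": "EX_co2", "metabolites": {"co2": -1}, "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "exchange: co2"},
    {"id": "EX_fe3", "metabolites": {"fe3": -1}, "lower_bound": -1000, "upper_bound": 0,
     "annotation": "exchange: fe3"},
    {"id": "EX_fe2", "metabolites": {"fe2": -1}, "lower_bound": 0, "upper_bound": 1000,
     "annotation": "exchange: fe2"},
    {"id": "EX_h2o", "metabolites": {"h2o": -1}, "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "exchange: h2o"},
    {"id": "EX_h", "metabolites": {"h": -1}, "lower_bound": -1000, "upper_bound": 1000,
     "annotation": "exchange: h"},
    {"id": "EX_ac", "metabolites": {"ac": -1}, "lower_bound": 0, "upper_bound": 1000,
     "annotation": "exchange: ac"},
    {"id": "EX_etoh", "metabolites": {"etoh": -1}, "lower_bound": 0, "upper_bound": 1000,
     "annotation": "exchange: etoh"},
    {"id": "EX_btoh", "metabolites": {"btoh": -1}, "lower_bound": 0, "upper_bound": 1000,
     "annotation": "exchange: btoh"}
  ]
}
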