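{
 "id": "a_succinogenes_core",
 "metabolites": [
  "glc",
  "pep",
  "pyr",
  "accoa",
  "oaa",
  "mal",
  "fum",
  "succ",
  "cit",
  "icit",
  "akg",
  "for",
  "ac",
  "co2",
  "atp",
  "adp",
  "nad",
  "nadh",
  "biomass"
 ],
 "reactions": [
  {
   "id": "GLYC",
   "stoichiometry": {
    "glc": -1,
    "nad": -2,
    "pep": 2,
    "nadh": 2
   },
   "reversible": false
  },
  {
   "id": "PYK",
   "stoichiometry": {
    "pep": -1,
    "adp": -1,
    "pyr": 1,
    "atp": 1
   },
   "reversible": false
  },
  {
   "id": "PPCK",
   "stoichiometry": {
    "pep": -1,
    "co2": -1,
    "adp": -1,
    "oaa": 1,
    "atp": 1
   },
   "reversible": false
  },
  {
   "id": "MDH",
   "stoichiometry": {
    "oaa": -1,
    "nadh": -1,
    "mal": 1,
    "nad": 1
   },
   "reversible": true
  },
  {
   "id": "FUMR",
   "stoichiometry": {
    "mal": -1,
    "fum": 1
   },
   "reversible": true
  },
  {
   "id": "FRD",
   "stoichiometry": {
    "fum": -1,
    "nadh": -1,
    "succ": 1,
    "nad": 1
   },
   "reversible": false
  },
  {
   "id": "PFL",
   "stoichiometry": {
    "pyr": -1,
    "accoa": 1,
    "for": 1
   },
   "reversible": false
  },
  {
   "id": "PDH",
   "stoichiometry": {
    "pyr": -1,
    "nad": -1,
    "accoa": 1,
    "co2": 1,
    "nadh": 1
   },
   "reversible": false
  },
  {
   "id": "PTAACK",
   "stoichiometry": {
    "accoa": -1,
    "adp": -1,
    "ac": 1,
    "atp": 1
   },
   "reversible": false
  },
  {
   "id": "CS",
   "stoichiometry": {
    "accoa": -1,
    "oaa": -1,
    "cit": 1
   },
   "reversible": false
  },
  {
   "id": "ACN",
   "stoichiometry": {
    "cit": -1,
    "icit": 1
   },
   "reversible": true
  },
  {
   "id": "ICDH",
   "stoichiometry": {
    "icit": -1,
    "nad": -1,
    "akg": 1,
    "co2": 1,
    "nadh": 1
   },
   "reversible": false
  },
  {
   "id": "AKGDH",
   "stoichiometry": {
    "akg": -1,
    "nad": -1,
    "adp": -1,
    "succ": 1,
    "co2": 1,
    "nadh": 1,
    "atp": 1
   },
   "reversible": false
  },
  {
   "id": "ATPM",
   "stoichiometry": {
    "atp": -1,
    "adp": 1
   },
   "reversible": false
  },
  {
   "id": "BIOMASS",
   "stoichiometry": {
    "pep": -3,
    "pyr": -3,
    "accoa": -4,
    "oaa": -2,
    "atp": -41.937799,
    "adp": 41.937799,
    "biomass": 1
   },
   "reversible": false
  },
  {
   "id": "EX_glc",
   "stoichiometry": {
    "glc": -1
   },
   "reversible": true
  },
  {
   "id": "EX_succ",
   "stoichiometry": {
    "succ": -1
   },
   "reversible": false
  },
  {
   "id": "EX_for",
   "stoichiometry": {
    "for": -1
   },
   "reversible": false
  },
  {
   "id": "EX_ac",
   "stoichiometry": {
    "ac": -1
   },
   "reversible": false
  },
  {
   "id": "EX_pyr",
   "stoichiometry": {
    "pyr": -1
   },
   "reversible": false
  },
  {
   "id": "EX_co2",
   "stoichiometry": {
    "co2": -1
   },
   "reversible": true
  },
  {
   "id": "EX_biomass",
   "stoichiometry": {
    "biomass": -1
   },
   "reversible": false
  }
 ],
 "biomass_id": "BIOMASS",
 "atp_demand_id": "ATPM",
 "boundary": {
  "species": [
   "biomass",
   "atp",
   "glc",
   "succ",
   "for",
   "ac",
   "pyr"
  ],
  "exchange_of": {
   "biomass": "EX_biomass",
   "atp": "ATPM",
   "glc": "EX_glc",
   "succ": "EX_succ",
   "for": "EX_for",
   "ac": "EX_ac",
   "pyr": "EX_pyr"
  },
  "units_of": {
   "biomass": "gDCW/L",
   "atp": "mmol/gDCW/h",
   "glc": "mM",
   "succ": "mM",
   "for": "mM",
   "ac": "mM",
   "pyr": "mM"
  },
  "product": "succ",
  "substrate": "glc",
  "flux_only": [
   "atp"
  ]
 },
 "description": "Lumped core-carbon reconstruction of Actinobacillus succinogenes fermentative metabolism: EMP glycolysis to PEP, the PEP carboxykinase reductive branch to succinate, pyruvate-node branches to formate/acetate/pyruvate, an oxidative citrate->2-oxoglutarate->succinate route, a single NAD(H) pool, ATP accounting with a non-growth ATP demand, and a lumped biomass reaction (1 flux unit = 1 gDCW) whose growth-ATP coefficient is calibrated to a biomass yield of 0.044 gDCW per mmol glucose at an uptake of 9.5 mmol/gDCW/h with 4.7 mmol/gDCW/h maintenance."
}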