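{
 "id": "toy_linear",
 "metabolites": [
  "A",
  "B"
 ],
 "reactions": [
  {
   "id": "EX_A",
   "stoichiometry": {
    "A": -1
   },
   "reversible": true
  },
  {
   "id": "CONV",
   "stoichiometry": {
    "A": -1,
    "B": 1
   },
   "reversible": false
  },
  {
   "id": "EX_B",
   "stoichiometry": {
    "B": -1
   },
   "reversible": false
  }
 ],
 "biomass_id": "CONV",
 "atp_demand_id": null
}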