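{
 "arcs": [
  {
   "category": "endogenous",
   "id": "R_acs>acetylCoA@Mmazei",
   "organism": "Mmazei",
   "reaction": "R_acs",
   "sources": [
    "acetate@Mmazei"
   ],
   "target": "acetylCoA@Mmazei",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_cdh>methylCoM@Mmazei",
   "organism": "Mmazei",
   "reaction": "R_cdh",
   "sources": [
    "acetylCoA@Mmazei"
   ],
   "target": "methylCoM@Mmazei",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_dhaB>3HPA@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_dhaB",
   "sources": [
    "glycerol@Kpneumoniae"
   ],
   "target": "3HPA@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_dhaT>PDO@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_dhaT",
   "sources": [
    "3HPA@Kpneumoniae"
   ],
   "target": "PDO@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_glpD>DHAP@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_glpD",
   "sources": [
    "glycerol3P@Kpneumoniae"
   ],
   "target": "DHAP@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_glpK>glycerol3P@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_glpK",
   "sources": [
    "glycerol@Kpneumoniae"
   ],
   "target": "glycerol3P@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_gpm>PEP@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_gpm",
   "sources": [
    "G3P@Kpneumoniae"
   ],
   "target": "PEP@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_mcr>methane@Mmazei",
   "organism": "Mmazei",
   "reaction": "R_mcr",
   "sources": [
    "methylCoM@Mmazei"
   ],
   "target": "methane@Mmazei",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_por>acetylCoA@Mmazei",
   "organism": "Mmazei",
   "reaction": "R_por",
   "sources": [
    "pyruvate@Mmazei"
   ],
   "target": "acetylCoA@Mmazei",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_poxB>acetate@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_poxB",
   "sources": [
    "pyruvate@Kpneumoniae"
   ],
   "target": "acetate@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_pyk>pyruvate@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_pyk",
   "sources": [
    "PEP@Kpneumoniae"
   ],
   "target": "pyruvate@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "endogenous",
   "id": "R_tpi>G3P@Kpneumoniae",
   "organism": "Kpneumoniae",
   "reaction": "R_tpi",
   "sources": [
    "DHAP@Kpneumoniae"
   ],
   "target": "G3P@Kpneumoniae",
   "weight": 1
  },
  {
   "category": "transition",
   "id": "tr:acetate:Kpneumoniae>Mmazei",
   "organism": [
    "Kpneumoniae",
    "Mmazei"
   ],
   "reaction": "transition:acetate",
   "sources": [
    "acetate@Kpneumoniae"
   ],
   "target": "acetate@Mmazei",
   "weight": 50
  },
  {
   "category": "transition",
   "id": "tr:acetate:Mmazei>Kpneumoniae",
   "organism": [
    "Mmazei",
    "Kpneumoniae"
   ],
   "reaction": "transition:acetate",
   "sources": [
    "acetate@Mmazei"
   ],
   "target": "acetate@Kpneumoniae",
   "weight": 50
  },
  {
   "category": "transition",
   "id": "tr:pyruvate:Kpneumoniae>Mmazei",
   "organism": [
    "Kpneumoniae",
    "Mmazei"
   ],
   "reaction": "transition:pyruvate",
   "sources": [
    "pyruvate@Kpneumoniae"
   ],
   "target": "pyruvate@Mmazei",
   "weight": 100
  },
  {
   "category": "transition",
   "id": "tr:pyruvate:Mmazei>Kpneumoniae",
   "organism": [
    "Mmazei",
    "Kpneumoniae"
   ],
   "reaction": "transition:pyruvate",
   "sources": [
    "pyruvate@Mmazei"
   ],
   "target": "pyruvate@Kpneumoniae",
   "weight": 100
  }
 ],
 "reference_reactions": [],
 "schema_version": 1,
 "sources": [
  "glycerol@Kpneumoniae"
 ],
 "targets": [
  "PDO@Kpneumoniae",
  "methane@Mmazei"
 ],
 "vertices": [
  {
   "compound": "3HPA",
   "id": "3HPA@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "DHAP",
   "id": "DHAP@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "G3P",
   "id": "G3P@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "PDO",
   "id": "PDO@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "PEP",
   "id": "PEP@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "acetate",
   "id": "acetate@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "acetate",
   "id": "acetate@Mmazei",
   "organism": "Mmazei"
  },
  {
   "compound": "acetylCoA",
   "id": "acetylCoA@Mmazei",
   "organism": "Mmazei"
  },
  {
   "compound": "glycerol3P",
   "id": "glycerol3P@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "glycerol",
   "id": "glycerol@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "methane",
   "id": "methane@Mmazei",
   "organism": "Mmazei"
  },
  {
   "compound": "methylCoM",
   "id": "methylCoM@Mmazei",
   "organism": "Mmazei"
  },
  {
   "compound": "pyruvate",
   "id": "pyruvate@Kpneumoniae",
   "organism": "Kpneumoniae"
  },
  {
   "compound": "pyruvate",
   "id": "pyruvate@Mmazei",
   "organism": "Mmazei"
  }
 ],
 "weights": {
  "overrides": [
   {
    "category": "transition",
    "key": "acetate",
    "weight": 50
   }
  ],
  "w_other": 100,
  "w_transition": 100,
  "w_worker": 1
 },
 "worker_organisms": [
  "Kpneumoniae",
  "Mmazei"
 ]
}
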