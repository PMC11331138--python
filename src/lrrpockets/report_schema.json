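{
 "type": "object",
 "required": ["meta", "stages"],
 "properties": {
  "meta": {
   "type": "object",
   "required": ["seed", "package", "statistic"]
  },
  "stages": {
   "type": "object",
   "properties": {
    "locus_mining": {"type": ["object", "null"]},
    "peptide_catalog": {"type": ["object", "null"]},
    "receptor_homology": {"type": ["object", "null"]},
    "rcm": {"type": ["object", "null"]},
    "complex_pockets": {"type": ["object", "null"]},
    "enrichment": {"type": ["object", "null"]}
   }
  }
 }
}
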