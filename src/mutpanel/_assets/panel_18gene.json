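{
  "name": "nsclc-ici-18gene",
  "version": "1.0",
  "genes": [
    "ZFHX3", "NTRK3", "EPHA7", "EPHA5", "NF2", "ABL1", "MAX", "PARP1",
    "PAX5", "PGR", "FLT3", "MRE11A", "PIK3C3", "INHBA", "RET", "EPHA3",
    "MET", "NOTCH1"
  ],
  "threshold_k": 2,
  "notes": "18-gene NSCLC immunotherapy-efficacy panel; samples with >= threshold_k mutated panel genes are called MT."
}
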