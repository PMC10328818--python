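{
 "seed": 101,
 "replicates": 5,
 "n_families": 300,
 "timepoints": [
  "3w",
  "3m",
  "12m"
 ],
 "values": {
  "tier_large@12m": {
   "R2": 0.08563130801446839,
   "R2_sd": 0.017241911703334754,
   "tolerance": 0.06896764681333901,
   "n_samples": 226.8
  },
  "tier_large@3m": {
   "R2": 0.06794216718865823,
   "R2_sd": 0.011435500894948927,
   "tolerance": 0.04574200357979571,
   "n_samples": 226.2
  },
  "tier_large@3w": {
   "R2": 0.0705915828387769,
   "R2_sd": 0.007980908439711705,
   "tolerance": 0.03192363375884682,
   "n_samples": 225.8
  },
  "tier_medium@12m": {
   "R2": 0.022856571686374526,
   "R2_sd": 0.005828572976463558,
   "tolerance": 0.023314291905854233,
   "n_samples": 226.8
  },
  "tier_medium@3m": {
   "R2": 0.020170394136632176,
   "R2_sd": 0.006240592547452205,
   "tolerance": 0.02496237018980882,
   "n_samples": 226.2
  },
  "tier_medium@3w": {
   "R2": 0.020869474650600052,
   "R2_sd": 0.00821554033341118,
   "tolerance": 0.03286216133364472,
   "n_samples": 225.8
  },
  "tier_none@12m": {
   "R2": 0.005177100294705611,
   "R2_sd": 0.002153655564040684,
   "tolerance": 0.008614622256162736,
   "n_samples": 226.8
  },
  "tier_none@3m": {
   "R2": 0.004115800451024611,
   "R2_sd": 0.001338508668712959,
   "tolerance": 0.005354034674851836,
   "n_samples": 226.2
  },
  "tier_none@3w": {
   "R2": 0.00493756383861173,
   "R2_sd": 0.002017667266596386,
   "tolerance": 0.008070669066385544,
   "n_samples": 225.8
  },
  "tier_small@12m": {
   "R2": 0.01065846477168011,
   "R2_sd": 0.0016590898823716635,
   "tolerance": 0.006636359529486654,
   "n_samples": 226.8
  },
  "tier_small@3m": {
   "R2": 0.01101535336121649,
   "R2_sd": 0.004754265937930612,
   "tolerance": 0.01901706375172245,
   "n_samples": 226.2
  },
  "tier_small@3w": {
   "R2": 0.012265482621819895,
   "R2_sd": 0.004586068801438684,
   "tolerance": 0.018344275205754736,
   "n_samples": 225.8
  }
 }
}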