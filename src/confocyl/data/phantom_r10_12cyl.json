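{
 "version": 1,
 "seed": 7,
 "slab": {
  "y": 200.0,
  "z": 200.0,
  "x": 200.0
 },
 "n_surround": 1.0,
 "achieved_fill": 0.09424777960769379,
 "cylinders": [
  {
   "cy": 22.51718398884006,
   "cz": 71.49848417452358,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": 49.62342424413484,
   "cz": -49.46270580169347,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": -35.97006871597942,
   "cz": 67.23962017132715,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": -89.05224517819654,
   "cz": 57.82111530889793,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": 53.47249717536832,
   "cz": -5.771708488130258,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": -35.454163172523565,
   "cz": -39.8833898218608,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": -44.12347422225757,
   "cz": -9.886264941123613,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": 0.8186866124315912,
   "cz": 9.629523373408645,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": 89.19005101819067,
   "cz": 52.679145458475546,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": -51.24443431759219,
   "cz": -61.16183390558798,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": 20.257128769145538,
   "cz": -82.090438566951,
   "r": 10.0,
   "n": 1.6285
  },
  {
   "cy": -83.5775498207527,
   "cz": 2.679987648846648,
   "r": 10.0,
   "n": 1.6285
  }
 ]
}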