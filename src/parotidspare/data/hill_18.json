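{
 "_comment": "SYNTHETIC Hill-ensemble parameters (declared ground truth for tests and demos, not clinical values). delta_i is proportional to the placeholder importance table and sums to 0.9 so predicted output stays in [0.1, 1]; D50 rises mildly with rank; n = 2.",
 "subsegments": [
  {
   "rank": 1,
   "delta": 0.183302,
   "d50_gy": 20.0,
   "n": 2.0
  },
  {
   "rank": 2,
   "delta": 0.146642,
   "d50_gy": 20.5,
   "n": 2.0
  },
  {
   "rank": 3,
   "delta": 0.117313,
   "d50_gy": 21.0,
   "n": 2.0
  },
  {
   "rank": 4,
   "delta": 0.093851,
   "d50_gy": 21.5,
   "n": 2.0
  },
  {
   "rank": 5,
   "delta": 0.075081,
   "d50_gy": 22.0,
   "n": 2.0
  },
  {
   "rank": 6,
   "delta": 0.060064,
   "d50_gy": 22.5,
   "n": 2.0
  },
  {
   "rank": 7,
   "delta": 0.048052,
   "d50_gy": 23.0,
   "n": 2.0
  },
  {
   "rank": 8,
   "delta": 0.038441,
   "d50_gy": 23.5,
   "n": 2.0
  },
  {
   "rank": 9,
   "delta": 0.030753,
   "d50_gy": 24.0,
   "n": 2.0
  },
  {
   "rank": 10,
   "delta": 0.024602,
   "d50_gy": 24.5,
   "n": 2.0
  },
  {
   "rank": 11,
   "delta": 0.019682,
   "d50_gy": 25.0,
   "n": 2.0
  },
  {
   "rank": 12,
   "delta": 0.015746,
   "d50_gy": 25.5,
   "n": 2.0
  },
  {
   "rank": 13,
   "delta": 0.012596,
   "d50_gy": 26.0,
   "n": 2.0
  },
  {
   "rank": 14,
   "delta": 0.010077,
   "d50_gy": 26.5,
   "n": 2.0
  },
  {
   "rank": 15,
   "delta": 0.008062,
   "d50_gy": 27.0,
   "n": 2.0
  },
  {
   "rank": 16,
   "delta": 0.006449,
   "d50_gy": 27.5,
   "n": 2.0
  },
  {
   "rank": 17,
   "delta": 0.005159,
   "d50_gy": 28.0,
   "n": 2.0
  },
  {
   "rank": 18,
   "delta": 0.004128,
   "d50_gy": 28.5,
   "n": 2.0
  }
 ]
}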