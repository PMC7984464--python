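{
 "_comment": "PLACEHOLDER importance table. Only the rank-1 anchor (3.85x the homogeneous-gland expectation, caudal-anterior) and the least-important subsegment being near zero are population-derived facts; the geometric decay (ratio 0.8) and the rank->octant layout beyond rank 1 are package defaults. Replace with published per-subsegment values for clinical use.",
 "subsegments": [
  {
   "rank": 1,
   "octant": {
    "cc_third": "caudal",
    "ap_third": "anterior",
    "ml_half": "medial"
   },
   "importance": 3.85
  },
  {
   "rank": 2,
   "octant": {
    "cc_third": "caudal",
    "ap_third": "anterior",
    "ml_half": "lateral"
   },
   "importance": 3.08
  },
  {
   "rank": 3,
   "octant": {
    "cc_third": "caudal",
    "ap_third": "mid",
    "ml_half": "medial"
   },
   "importance": 2.464
  },
  {
   "rank": 4,
   "octant": {
    "cc_third": "caudal",
    "ap_third": "mid",
    "ml_half": "lateral"
   },
   "importance": 1.9712
  },
  {
   "rank": 5,
   "octant": {
    "cc_third": "caudal",
    "ap_third": "posterior",
    "ml_half": "medial"
   },
   "importance": 1.57696
  },
  {
   "rank": 6,
   "octant": {
    "cc_third": "caudal",
    "ap_third": "posterior",
    "ml_half": "lateral"
   },
   "importance": 1.261568
  },
  {
   "rank": 7,
   "octant": {
    "cc_third": "mid",
    "ap_third": "anterior",
    "ml_half": "medial"
   },
   "importance": 1.009254
  },
  {
   "rank": 8,
   "octant": {
    "cc_third": "mid",
    "ap_third": "anterior",
    "ml_half": "lateral"
   },
   "importance": 0.807404
  },
  {
   "rank": 9,
   "octant": {
    "cc_third": "mid",
    "ap_third": "mid",
    "ml_half": "medial"
   },
   "importance": 0.645923
  },
  {
   "rank": 10,
   "octant": {
    "cc_third": "mid",
    "ap_third": "mid",
    "ml_half": "lateral"
   },
   "importance": 0.516738
  },
  {
   "rank": 11,
   "octant": {
    "cc_third": "mid",
    "ap_third": "posterior",
    "ml_half": "medial"
   },
   "importance": 0.413391
  },
  {
   "rank": 12,
   "octant": {
    "cc_third": "mid",
    "ap_third": "posterior",
    "ml_half": "lateral"
   },
   "importance": 0.330712
  },
  {
   "rank": 13,
   "octant": {
    "cc_third": "cranial",
    "ap_third": "anterior",
    "ml_half": "medial"
   },
   "importance": 0.26457
  },
  {
   "rank": 14,
   "octant": {
    "cc_third": "cranial",
    "ap_third": "anterior",
    "ml_half": "lateral"
   },
   "importance": 0.211656
  },
  {
   "rank": 15,
   "octant": {
    "cc_third": "cranial",
    "ap_third": "mid",
    "ml_half": "medial"
   },
   "importance": 0.169325
  },
  {
   "rank": 16,
   "octant": {
    "cc_third": "cranial",
    "ap_third": "mid",
    "ml_half": "lateral"
   },
   "importance": 0.13546
  },
  {
   "rank": 17,
   "octant": {
    "cc_third": "cranial",
    "ap_third": "posterior",
    "ml_half": "medial"
   },
   "importance": 0.108368
  },
  {
   "rank": 18,
   "octant": {
    "cc_third": "cranial",
    "ap_third": "posterior",
    "ml_half": "lateral"
   },
   "importance": 0.086694
  }
 ]
}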