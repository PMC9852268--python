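{
 "format": "vfprog-agis-tables",
 "version": 1,
 "note": "Sector membership and scoring bins follow the published AGIS structure (nasal 0-2, each hemifield 0-9, total 0-20); per-site depth cutoffs are an eccentricity-based approximation of the trial's site map and are replaceable via this file.",
 "sites": [
  {
   "x": -9,
   "y": 21,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": -3,
   "y": 21,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": 3,
   "y": 21,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": 9,
   "y": 21,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": -15,
   "y": 15,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": -9,
   "y": 15,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": -3,
   "y": 15,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": 3,
   "y": 15,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": 9,
   "y": 15,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": 15,
   "y": 15,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": -21,
   "y": 9,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": -15,
   "y": 9,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": -9,
   "y": 9,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": -3,
   "y": 9,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": 3,
   "y": 9,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": 9,
   "y": 9,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": 15,
   "y": 9,
   "sector": "upper",
   "depth_db": 7.0
  },
  {
   "x": 21,
   "y": 9,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": -27,
   "y": 3,
   "sector": "nasal",
   "depth_db": 5.0
  },
  {
   "x": -21,
   "y": 3,
   "sector": "nasal",
   "depth_db": 5.0
  },
  {
   "x": -15,
   "y": 3,
   "sector": "nasal",
   "depth_db": 5.0
  },
  {
   "x": -9,
   "y": 3,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": -3,
   "y": 3,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": 3,
   "y": 3,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": 9,
   "y": 3,
   "sector": "upper",
   "depth_db": 6.0
  },
  {
   "x": 21,
   "y": 3,
   "sector": "upper",
   "depth_db": 8.0
  },
  {
   "x": -27,
   "y": -3,
   "sector": "nasal",
   "depth_db": 5.0
  },
  {
   "x": -21,
   "y": -3,
   "sector": "nasal",
   "depth_db": 5.0
  },
  {
   "x": -15,
   "y": -3,
   "sector": "nasal",
   "depth_db": 5.0
  },
  {
   "x": -9,
   "y": -3,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": -3,
   "y": -3,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": 3,
   "y": -3,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": 9,
   "y": -3,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": 21,
   "y": -3,
   "sector": "lower",
   "depth_db": 8.0
  },
  {
   "x": -21,
   "y": -9,
   "sector": "lower",
   "depth_db": 8.0
  },
  {
   "x": -15,
   "y": -9,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": -9,
   "y": -9,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": -3,
   "y": -9,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": 3,
   "y": -9,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": 9,
   "y": -9,
   "sector": "lower",
   "depth_db": 6.0
  },
  {
   "x": 15,
   "y": -9,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": 21,
   "y": -9,
   "sector": "lower",
   "depth_db": 8.0
  },
  {
   "x": -15,
   "y": -15,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": -9,
   "y": -15,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": -3,
   "y": -15,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": 3,
   "y": -15,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": 9,
   "y": -15,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": 15,
   "y": -15,
   "sector": "lower",
   "depth_db": 7.0
  },
  {
   "x": -9,
   "y": -21,
   "sector": "lower",
   "depth_db": 8.0
  },
  {
   "x": -3,
   "y": -21,
   "sector": "lower",
   "depth_db": 8.0
  },
  {
   "x": 3,
   "y": -21,
   "sector": "lower",
   "depth_db": 8.0
  },
  {
   "x": 9,
   "y": -21,
   "sector": "lower",
   "depth_db": 8.0
  }
 ],
 "nasal_rules": {
  "min_contiguous": 3,
  "deep_all_db": 12.0,
  "cap": 2,
  "contiguity_crosses_midline": true
 },
 "hemifield_rules": {
  "cluster_min": 3,
  "count_bins": [
   [
    6,
    12,
    1
   ],
   [
    13,
    20,
    2
   ],
   [
    21,
    23,
    3
   ]
  ],
  "depth_increments_db": [
   12.0,
   16.0,
   20.0,
   24.0,
   28.0
  ],
  "depth_fraction": 0.5,
  "cap": 9,
  "contiguity_crosses_midline": false
 }
}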