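{
 "comment": "Per-tissue mean intensities of the synthetic abdominal phantom, one row per class. 'ct' is HU-like; 't1'/'t2' are arbitrary MR-like units. T1w means for density-mapped tissues follow t1 = 1045 - ct (a monotone decreasing map of tissue density), so that intensity inversion within the volume range reproduces CT-like values; fat and gallbladder sit at the top of the T1w scale, lungs near the bottom. 'noise_scale' multiplies the case noise SD (lungs are noisier). These are package defaults, not literature values.",
 "classes": [
  {
   "id": 1,
   "name": "lung_left",
   "ct": -700,
   "t1": 20,
   "t2": 50,
   "noise_scale": 1.5
  },
  {
   "id": 2,
   "name": "lung_right",
   "ct": -700,
   "t1": 20,
   "t2": 50,
   "noise_scale": 1.5
  },
  {
   "id": 3,
   "name": "fat",
   "ct": -120,
   "t1": 1000,
   "t2": 40,
   "noise_scale": 1.0
  },
  {
   "id": 4,
   "name": "muscle",
   "ct": 140,
   "t1": 905,
   "t2": 85,
   "noise_scale": 1.0
  },
  {
   "id": 5,
   "name": "liver",
   "ct": 240,
   "t1": 805,
   "t2": 240,
   "noise_scale": 1.0
  },
  {
   "id": 6,
   "name": "spleen",
   "ct": 340,
   "t1": 705,
   "t2": 340,
   "noise_scale": 1.0
  },
  {
   "id": 7,
   "name": "kidney_left",
   "ct": 430,
   "t1": 615,
   "t2": 425,
   "noise_scale": 1.0
  },
  {
   "id": 8,
   "name": "kidney_right",
   "ct": 430,
   "t1": 615,
   "t2": 425,
   "noise_scale": 1.0
  },
  {
   "id": 9,
   "name": "aorta",
   "ct": 640,
   "t1": 405,
   "t2": 150,
   "noise_scale": 1.0
  },
  {
   "id": 10,
   "name": "bone",
   "ct": 1000,
   "t1": 45,
   "t2": 60,
   "noise_scale": 1.0
  },
  {
   "id": 11,
   "name": "gallbladder",
   "ct": -40,
   "t1": 985,
   "t2": 620,
   "noise_scale": 1.0
  },
  {
   "id": 12,
   "name": "tumor",
   "ct": 500,
   "t1": 565,
   "t2": 580,
   "noise_scale": 1.0
  }
 ],
 "background": {
  "ct": -1000,
  "t1": 0,
  "t2": 0
 }
}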