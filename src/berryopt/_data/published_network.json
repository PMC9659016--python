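{
 "provenance": "published 3-8-4 tansig/pureline network, printed weights; inputs min-max scaled over optimization bounds | output transforms least-squares calibrated against the published 30-point Pareto front (frozen)",
 "topology": {
  "hidden_neurons": 8,
  "hidden_activation": "tansig",
  "output_activation": "pureline"
 },
 "hidden_weights": [
  [
   -0.3826,
   1.0233,
   0.1616
  ],
  [
   -2.2399,
   -0.2557,
   -0.2111
  ],
  [
   1.3779,
   -0.8164,
   -2.1741
  ],
  [
   -0.4903,
   -0.1129,
   -1.0111
  ],
  [
   1.583,
   0.0897,
   -0.0504
  ],
  [
   -0.2677,
   -0.2317,
   2.3441
  ],
  [
   -0.4421,
   1.0577,
   0.1488
  ],
  [
   0.1699,
   -3.7173,
   -0.1564
  ]
 ],
 "hidden_bias": [
  0.8245,
  1.3641,
  0.1381,
  0.5771,
  0.8454,
  1.2737,
  -1.5383,
  3.7802
 ],
 "output_weights": [
  [
   -0.3917,
   0.3925,
   -0.0601,
   -0.4614,
   -0.5823,
   -0.31,
   -0.4336,
   0.0142
  ],
  [
   -0.6254,
   0.2887,
   -0.1322,
   -0.3637,
   -0.5103,
   -0.1851,
   -1.2531,
   -0.2409
  ],
  [
   1.0117,
   0.1953,
   0.0236,
   0.1323,
   0.781,
   0.0119,
   1.5636,
   1.2447
  ],
  [
   0.7483,
   0.2663,
   0.0102,
   0.005,
   0.6852,
   -0.0594,
   0.6438,
   0.4402
  ]
 ],
 "output_bias": [
  0.1802,
  -0.2779,
  -0.6516,
  -0.5921
 ],
 "input_transforms": [
  {
   "gain": 45.0,
   "offset": 75.0
  },
  {
   "gain": 20.0,
   "offset": 70.0
  },
  {
   "gain": 1.245,
   "offset": 1.255
  }
 ],
 "output_transforms": [
  {
   "gain": 490.80184559443694,
   "offset": 734.5274885865897
  },
  {
   "gain": 6.156715268143662,
   "offset": 6.69314116184463
  },
  {
   "gain": 1.3892201510967837,
   "offset": 3.4498278514299003
  },
  {
   "gain": -0.6131526501992345,
   "offset": 3.654409292955735
  }
 ]
}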