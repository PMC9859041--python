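{
 "1": {
  "mean": [
   28.005152,
   1.209413,
   0.356,
   0.612379,
   0.392948,
   -0.814863
  ],
  "covariance": [
   [
    8.67298326,
    -0.00046621,
    -0.01337851,
    -0.02466985,
    -0.02497105,
    0.09747
   ],
   [
    -0.00046621,
    0.21063703,
    -0.00132245,
    0.02330994,
    0.00748378,
    0.01175034
   ],
   [
    -0.01337851,
    -0.00132245,
    0.01986501,
    0.00031671,
    -0.0013722,
    0.00116672
   ],
   [
    -0.02466985,
    0.02330994,
    0.00031671,
    0.2720279,
    -0.00180344,
    -0.00243257
   ],
   [
    -0.02497105,
    0.00748378,
    -0.0013722,
    -0.00180344,
    0.02154709,
    0.00351458
   ],
   [
    0.09747,
    0.01175034,
    0.00116672,
    -0.00243257,
    0.00351458,
    0.27204648
   ]
  ],
  "n_samples": 300
 },
 "2": {
  "mean": [
   27.893696,
   1.184959,
   0.359431,
   0.596204,
   0.383964,
   -0.809438
  ],
  "covariance": [
   [
    9.72484087,
    0.06082372,
    -0.04172919,
    -0.12675214,
    -0.02199823,
    -0.08087283
   ],
   [
    0.06082372,
    0.22090117,
    0.00217894,
    -0.00578396,
    -0.00020801,
    -0.04780889
   ],
   [
    -0.04172919,
    0.00217894,
    0.02415978,
    0.00092558,
    0.00092976,
    0.00470676
   ],
   [
    -0.12675214,
    -0.00578396,
    0.00092558,
    0.22984765,
    -0.00071374,
    -0.01090719
   ],
   [
    -0.02199823,
    -0.00020801,
    0.00092976,
    -0.00071374,
    0.02306317,
    -0.00581344
   ],
   [
    -0.08087283,
    -0.04780889,
    0.00470676,
    -0.01090719,
    -0.00581344,
    0.24195241
   ]
  ],
  "n_samples": 300
 },
 "_comment": "Synthetic per-MHC-class docking-geometry priors (mean and covariance of the 6-parameter vectors) fit to geometries sampled around the consensus docking mode; stand-ins for distributions fit to solved-structure databases."
}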