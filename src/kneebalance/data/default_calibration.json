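{
 "profiles": {
  "ARCUATE_RELEASE": {
   "mean_delta": [
    0.0,
    -8.0,
    0.0,
    0.0,
    -1.5,
    -1.0
   ],
   "significant": [
    false,
    true,
    false,
    false,
    true,
    true
   ]
  },
  "FEMUR_RECUT": {
   "mean_delta": [
    -5.0,
    -2.0,
    0.0,
    0.0,
    0.0,
    -3.0
   ],
   "significant": [
    false,
    false,
    false,
    false,
    false,
    true
   ]
  },
  "INSERT_UP_2MM": {
   "mean_delta": [
    4.0,
    4.0,
    3.0,
    3.0,
    0.0,
    2.5
   ],
   "significant": [
    true,
    true,
    false,
    false,
    false,
    true
   ]
  },
  "ITB_RELEASE": {
   "mean_delta": [
    0.0,
    -6.0,
    0.0,
    0.0,
    0.0,
    0.0
   ],
   "significant": [
    false,
    true,
    false,
    false,
    false,
    false
   ]
  },
  "MCL_PIECRUST": {
   "mean_delta": [
    -10.0,
    3.0,
    -10.0,
    3.0,
    1.75,
    -0.5
   ],
   "significant": [
    true,
    true,
    true,
    true,
    true,
    true
   ]
  },
  "POPLITEUS_RELEASE": {
   "mean_delta": [
    0.0,
    -4.0,
    0.0,
    -8.0,
    -1.0,
    0.0
   ],
   "significant": [
    false,
    true,
    false,
    true,
    true,
    false
   ]
  },
  "POSTERIOR_CAPSULE_RELEASE": {
   "mean_delta": [
    -3.0,
    0.0,
    0.0,
    0.0,
    0.0,
    -2.5
   ],
   "significant": [
    true,
    false,
    false,
    false,
    false,
    true
   ]
  },
  "TIBIA_RECUT": {
   "mean_delta": [
    -8.0,
    0.0,
    -8.0,
    -3.0,
    -1.5,
    -2.0
   ],
   "significant": [
    true,
    false,
    true,
    true,
    true,
    true
   ]
  }
 },
 "sigma_patient": [
  1.0,
  1.0,
  1.0,
  1.0,
  0.3,
  0.3
 ],
 "sigma_resid": [
  1.5,
  1.5,
  1.5,
  1.5,
  0.4,
  0.4
 ]
}
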