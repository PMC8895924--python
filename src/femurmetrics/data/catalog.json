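{
 "schema_version": 1,
 "implants": [
  {
   "name": "Gamma 3",
   "nsa_options_deg": [120, 125, 130],
   "curvature_radii_m": [1.5, 2.0],
   "lag_screw_min_mm": 70,
   "lag_screw_max_mm": 130,
   "builtin_anteversion_deg": 10,
   "gt_to_slsni_options_mm": [38.4, 42, 46]
  },
  {
   "name": "Intertan",
   "nsa_options_deg": [125, 130],
   "curvature_radii_m": [1.5],
   "lag_screw_min_mm": 70,
   "lag_screw_max_mm": 125,
   "builtin_anteversion_deg": 12,
   "gt_to_slsni_options_mm": [35.6]
  }
 ]
}
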