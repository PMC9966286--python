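{
 "factors": [
  {
   "name": "ethanol",
   "center": 50.0,
   "step": 25.0,
   "axial_low": 0.0,
   "axial_high": 100.0,
   "units": "%"
  },
  {
   "name": "time",
   "center": 82.5,
   "step": 37.5,
   "axial_low": 15.0,
   "axial_high": 150.0,
   "units": "min"
  },
  {
   "name": "temperature",
   "center": 60.0,
   "step": 10.0,
   "axial_low": 40.0,
   "axial_high": 80.0,
   "units": "degC"
  }
 ],
 "n_center": 6,
 "responses": {
  "TPC": "mgGAE/g",
  "TFC": "mgCAE/g"
 }
}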