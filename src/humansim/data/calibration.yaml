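presets:
  internal_hemorrhage:
    rate_ml_per_min: 63.1731
  tamponade:
    rate_ml_per_min: 2.1916
  burn_airway:
    tau_s: 6634.513
  burn_chest_circumferential:
    tau_s: 3668.5315
  tbi_hemorrhage:
    rate_ml_per_min: 0.9543
config:
  resp:
    o2_store_per_kg: 27.7326
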