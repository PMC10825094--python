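# Inhaled-sedation device catalog.
# geometric_volume_mL: internal (volumetric) dead space of the filter.
# etco2_increase_pct: mean EtCO2 rise observed after insertion at the
#   reference bench settings (VT 400 mL, RR 20/min, circuit dead space
#   120 mL, baseline EtCO2 40 mmHg), with its standard deviation.
# Added resistances default to 0: pressures are measured downstream of the
# device, so its resistive pressure is excluded from the indices.
fesevo_target: 0.013
devices:
  - name: ANA-50
    geometric_volume_mL: 50.0
    etco2_increase_pct: 49.0
    etco2_increase_sd_pct: 7.0
    resistance_insp: 0.0
    resistance_exp: 0.0
  - name: MIRUS
    geometric_volume_mL: 100.0
    etco2_increase_pct: 78.0
    etco2_increase_sd_pct: 13.0
    resistance_insp: 0.0
    resistance_exp: 0.0
  - name: ANA-100
    geometric_volume_mL: 100.0
    etco2_increase_pct: 100.0
    etco2_increase_sd_pct: 11.0
    resistance_insp: 0.0
    resistance_exp: 0.0
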