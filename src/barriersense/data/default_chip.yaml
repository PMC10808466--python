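# Default chip configuration.
#
# SYNTHETIC GEOMETRY: the published chip text states only the membrane
# thickness (20 um); the remaining dimensions here are synthetic stand-ins
# chosen once to be physically plausible for a laser-cut PMMA two-channel
# chip and consistent (to 3 s.f.) with a wall shear stress of
# 30.7e-3 dynes/cm^2 at 100 uL/min. Replace with measured values from your
# own chip design before interpreting absolute transport predictions.
geometry:
  channel_width_cm: 0.3         # flow channel width w
  channel_height_cm: 0.0866     # flow channel height h
  capillary_height_cm: 0.0866   # fluid column height above the membrane
  membrane_thickness_um: 20.0   # PCTE membrane
  exposed_area_cm2: 0.6         # membrane area open to both channels
  capillary_volume_ml: 0.052    # capillary channel volume Vc
  filtrate_volume_ml: 0.08      # filtrate channel volume Vf

fluid:                          # water at 37 degC
  viscosity_poise: 0.006913
  density_g_per_cm3: 0.9933
  temperature_K: 310.15

tracers:
  - name: inulin-FITC
    molecular_weight: 5000.0    # g/mol, free inulin; conjugate MW is a choice
    permeability_um2: 2.01e-4
    channel: cyan
  - name: HSA-TexasRed
    molecular_weight: 68000.0
    permeability_um2: 9.67e-4
    channel: amber

rois:                           # [row_start, row_end, col_start, col_end)
  capillary: [0, 380, 60, 220]
  filtrate: [0, 380, 287, 447]

schedule:
  period_s: 120.0
  duration_s: 600.0
  min_period_s: 7.0

transient:
  tau_s: 120.0                  # filtrate compartment time constant

seed: 0
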