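# Published operating point: 10 uA step infusion for 40 min, no hydrolysis.
current: 10 uA
duration: 40 min
output_interval: 30 s
resolution: 1
temperature_context: 37
dialysate_inflow: 0.5 uL/min
infused_concentration: 1 mM
reaction:
  k: 0 1/s            # or give vmax + km instead
  substrate: YGGFL
  product: GGFL
# geometry overrides (all published dimensions are defaults), e.g.:
# geometry:
#   source_sink_vertical_offset: 50 um
# material overrides per medium (tissue, membrane, fluidic_channels,
# infused_solution), e.g.:
# materials:
#   tissue:
#     porosity_alpha: 0.25
#     zeta_potential: -20 mV
tissue_farfield: absorbing
farfield_shell: 0.1 mm
seed: 0
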