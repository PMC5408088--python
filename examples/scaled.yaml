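# Desk-scale vascular factory run: 258 x 258 um, 3000 interior cells.
# Any SimulationConfig field can be overridden here; diffusion
# coefficients are in m^2/s and converted internally.
profile: scaled
seed: 1
vascular_fraction: 0.30
chemo_params:
  D_c: 1.0e-13
factory_params:
  D_p: 2.0e-11
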