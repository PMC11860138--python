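# Atractylodin (active marker of Atractylodes lancea extract).
# Binding/permeability values are documented placeholders; the kinetic free
# parameters in pbpk_params.yaml are calibrated against the clinical table.
name: atractylodin
mw: 182.22            # g/mol
log_p: 3.8
pka: 9.9              # effectively non-ionised at intestinal pH
fu: 0.10              # unbound plasma fraction
rbp: 1.5              # blood-to-plasma ratio
papp: 2.0e-5          # apparent permeability, cm/s
solubility: 0.012     # mg/mL (poorly soluble polyacetylene)
extract_fraction: 0.14
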