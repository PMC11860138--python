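# Tissue-to-plasma partition coefficients (placeholder set, globally
# rescaled by the calibrated kp_scalar).
lung: 1.0
heart: 1.5
brain: 1.5
muscle: 1.0
adipose: 1.5
skin: 1.5
bone: 0.8
kidney: 2.0
spleen: 1.5
gut: 2.0
liver: 4.0
rest: 1.2
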