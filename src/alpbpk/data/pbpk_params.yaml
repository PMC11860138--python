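# Calibrated kinetic parameters (seeded calibration against the printed
# clinical NCA table; see docs/methods.md).
ka: 1.437                # 1/h
f_abs: 0.527
cl_int_hepatic: 639.7  # L/h
kp_scalar: 1.769
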