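# Default virtual subject (healthy adult, fasting).
body_weight: 60.0   # kg
age: 40.0           # years
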