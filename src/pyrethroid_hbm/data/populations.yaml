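# Daily urine volume adjusted to body weight, L per kg bw per day
# (German HBM Commission convention adopted for the aligned studies).
children: 0.03
adults: 0.02
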