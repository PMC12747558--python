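compound	rate
nh4	10
pi	10
so4	10
mg2	10
fe2	10
h2o	10
h	10
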