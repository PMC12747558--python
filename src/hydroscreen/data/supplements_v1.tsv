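supplement_id	name
s1_biotin	biotin
s2_thiamine	thiamine
s3_cobalamin	cobalamin
s4_nicotinate	nicotinate
s5_pantothenate	pantothenate
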