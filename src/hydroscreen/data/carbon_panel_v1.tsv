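carbon_id	name	class
c01_glucose	D-glucose	sugar
c02_fructose	D-fructose	sugar
c03_galactose	D-galactose	sugar
c04_mannose	D-mannose	sugar
c05_xylose	D-xylose	sugar
c06_arabinose	L-arabinose	sugar
c07_ribose	D-ribose	sugar
c08_rhamnose	L-rhamnose	sugar
c09_fucose	L-fucose	sugar
c10_sucrose	sucrose	sugar
c11_maltose	maltose	sugar
c12_lactose	lactose	sugar
c13_cellobiose	cellobiose	sugar
c14_trehalose	trehalose	sugar
c15_melibiose	melibiose	sugar
c16_raffinose	raffinose	sugar
c17_glcnac	N-acetyl-D-glucosamine	sugar
c18_acetate	acetate	organic acid
c19_lactate	DL-lactate	organic acid
c20_pyruvate	pyruvate	organic acid
c21_succinate	succinate	organic acid
c22_fumarate	fumarate	organic acid
c23_malate	L-malate	organic acid
c24_citrate	citrate	organic acid
c25_propionate	propionate	organic acid
c26_formate	formate	organic acid
c27_gluconate	D-gluconate	organic acid
c28_glucuronate	D-glucuronate	organic acid
c29_galacturonate	D-galacturonate	organic acid
c30_akg	2-oxoglutarate	organic acid
c31_glycerol	glycerol	sugar alcohol
c32_mannitol	D-mannitol	sugar alcohol
c33_sorbitol	D-sorbitol	sugar alcohol
c34_xylitol	xylitol	sugar alcohol
c35_arabitol	D-arabitol	sugar alcohol
c36_inositol	myo-inositol	sugar alcohol
c37_alanine	L-alanine	amino acid
c38_glycine	glycine	amino acid
c39_serine	L-serine	amino acid
c40_threonine	L-threonine	amino acid
c41_aspartate	L-aspartate	amino acid
c42_glutamate	L-glutamate	amino acid
c43_asparagine	L-asparagine	amino acid
c44_glutamine	L-glutamine	amino acid
c45_proline	L-proline	amino acid
c46_valine	L-valine	amino acid
c47_leucine	L-leucine	amino acid
c48_isoleucine	L-isoleucine	amino acid
c49_lysine	L-lysine	amino acid
c50_arginine	L-arginine	amino acid
c51_histidine	L-histidine	amino acid
c52_methionine	L-methionine	amino acid
c53_tryptophan	L-tryptophan	amino acid
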