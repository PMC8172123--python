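{
 "seed": 20210519,
 "n_replicates": 150,
 "n_iterations": 7,
 "refine_replicates": 400,
 "refine_span": 0.12,
 "genes": [
  1.7741000791139239,
  -0.3548200158227848,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.4730933544303797,
  1.7741000791139239,
  0.3548200158227848,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.23654667721518985,
  0.0,
  0.3548200158227848,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.9461867088607594,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.5913666930379746,
  0.0,
  1.419280063291139,
  -0.2956833465189873,
  0.0,
  0.0,
  0.5913666930379746,
  0.0,
  0.0,
  0.0,
  0.3548200158227848,
  1.1827333860759492,
  0.4730933544303797,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.3548200158227848,
  0.0,
  0.0,
  0.0,
  0.0,
  0.7096400316455695,
  0.0,
  0.0,
  0.0,
  0.0,
  0.3548200158227848,
  0.0,
  0.0,
  -0.7096400316455695,
  0.0,
  0.0,
  0.0,
  0.8279133702531645,
  0.0,
  0.0,
  0.0,
  0.3548200158227848,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.5913666930379746,
  0.0,
  0.0,
  0.23654667721518985,
  0.0,
  0.0,
  0.7096400316455695,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0
 ]
}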