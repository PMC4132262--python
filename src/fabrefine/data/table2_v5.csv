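mutation,location,ddg_parental,ddg_model,direction,phenotype
LC:K24R,CDR L1,-0.21,-0.17,humanizing,Human
LC:S56T,CDR L2,-0.05,0.04,humanizing,Human
LC:V58I,Framework,-0.64,0.01,humanizing,Human
HC:I20L,Framework,0.43,-0.86,humanizing,Human
HC:A62S,CDR H2,-0.24,-0.5,humanizing,Human
HC:F63V,CDR H2,1.91,1.8,humanizing,Human
HC:M64K,CDR H2,0.1,-0.23,humanizing,Human
HC:S65G,CDR H2,0.82,1.1,humanizing,Human
HC:M89V,Framework,-0.5,-0.29,humanizing,Human
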