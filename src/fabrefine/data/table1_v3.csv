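mutation,location,ddg_parental,ddg_model,direction,phenotype
LC:E1S,Framework,-0.48,0.28,back,Murine
LC:T10F,Framework,0.17,-0.95,back,Murine
LC:S12L,Framework,-1.26,0.79,back,Murine
LC:K24R,CDR L1,-0.21,-0.17,humanizing,Human
LC:P40A,Framework,0.22,1.41,back,Murine
LC:S56T,CDR L2,-0.05,0.04,humanizing,Human
LC:V58I,Framework,-0.64,0.01,humanizing,Human
LC:Q100G,Framework,1.06,2.94,back,Murine
HC:V11L,Framework,-1.61,0.99,back,Murine
HC:I20L,Framework,0.43,-0.86,humanizing,Human
HC:S21T,Framework,-0.68,0.42,back,Murine
HC:M89V,Framework,-0.5,-0.29,humanizing,Human
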