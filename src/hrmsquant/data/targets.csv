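name,formula,rt_min,fragment_mz,group,mrl_ng_g,residue_class
trimethoprim,C14H18N4O3,0.83,123.0592,B,50,trimethoprim
sulfapyridine,C11H11N3O2S,1.08,156.0128,B,100,sulfonamide
sulfamerazine,C11H12N4O2S,1.18,108.0483,B,100,sulfonamide
sulfathiazole,C9H9N3O2S2,0.99,156.0127,B,100,sulfonamide
sulfamethazine,C12H14N4O2S,1.25,108.0475,B,100,sulfonamide
sulfadimethoxine,C12H14N4O4S,2.19,156.0771,B,100,sulfonamide
sulfamethoxazole,C10H11N3O3S,1.81,156.0124,B,100,sulfonamide
sulfamethoxypyridazine,C11H12N4O3S,1.44,156.0125,B,100,sulfonamide
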