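name,slope,recovery,matrix_effect
trimethoprim,1588.92,0.906,0.0317
sulfapyridine,1174.07,0.930,-0.0575
sulfamerazine,1345.72,0.820,-0.0101
sulfathiazole,633.811,0.442,0.0187
sulfamethazine,2324.3,0.698,-0.0345
sulfadimethoxine,2670.56,0.494,-0.0175
sulfamethoxazole,1626.52,0.436,-0.0195
sulfamethoxypyridazine,2057.08,0.705,0.0305
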