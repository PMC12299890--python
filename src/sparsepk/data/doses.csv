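subject_id,body_weight_g,dose_mg
rat1,410.0,4.1
rat2,424.8,4.25
rat3,374.7,3.75
rat4,371.1,3.71
rat5,405.7,4.06
rat6,366.2,3.66
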