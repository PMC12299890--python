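subject_id,time_h,conc_mg_per_L
rat1,0,BLQ
rat1,0.25,BLQ
rat1,0.5,1
rat1,1,1.6
rat1,1.5,7.2
rat1,12,BLQ
rat1,24,BLQ
rat2,0,BLQ
rat2,0.25,BLQ
rat2,0.5,4.6
rat2,1,5.6
rat2,1.5,6.2
rat2,12,BLQ
rat2,24,BLQ
rat3,0,BLQ
rat3,0.25,BLQ
rat3,0.5,5.6
rat3,1,6.8
rat3,1.5,4.4
rat3,12,BLQ
rat3,24,BLQ
rat4,2,3.2
rat4,4,0.6
rat4,8,0.4
rat4,36,BLQ
rat4,48,BLQ
rat5,2,3.8
rat5,4,6.1
rat5,8,0.2
rat5,36,BLQ
rat5,48,BLQ
rat6,2,5.4
rat6,4,3.6
rat6,8,0.4
rat6,36,BLQ
rat6,48,BLQ
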