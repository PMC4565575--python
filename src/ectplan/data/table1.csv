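metastasis,pair,voltage_v,i_meas_a,i_comp_a,error_printed_pct
1,1-2,1200,21.5,22.6,5
1,1-4,1200,20.7,20.4,-1
1,2-3,1200,17.6,19.5,11
1,3-4,1200,20.9,21.2,1
1,2-5,1000,17.8,21.1,19
1,1-5,1000,23.5,22,-6
1,3-5,1000,17.8,20.2,13
1,4-5,1000,16.2,19.5,20
2,1-2,1200,22.2,18.4,-17
2,1-4,1200,17.6,15.5,-12
2,2-3,1200,20.2,17.5,-13
2,3-4,1200,17.6,22.2,26
2,2-5,1000,17.8,17.1,-4
2,1-5,1000,17.2,20,16
2,3-5,1000,16.1,15.6,-3
2,4-5,1000,12.6,19.9,58
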