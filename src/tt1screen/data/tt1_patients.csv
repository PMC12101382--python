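record_id,assay,sa_cov_original,sa,tyr,phe,diagnosis,original_result
TT1-01,NeoBase,1.50,4.93,829,81,TT1,positive
TT1-02,NeoBase,1.20,4.37,439,78,TT1,positive
TT1-03,NeoBase,1.20,1.08,288,68,TT1,negative
TT1-04,NeoBase,1.20,6.70,833,137,TT1,positive
TT1-05,NeoBase,1.20,7.96,416,55,TT1,positive
TT1-06,NeoBase,1.20,5.13,493,47,TT1,positive
TT1-07,NeoBase,1.20,5.48,500,60,TT1,positive
TT1-08,NeoBase,1.20,1.90,900,64,TT1,positive
TT1-09,NeoBase,1.20,16.93,236,56,TT1,positive
TT1-10,NeoBase,1.20,5.32,569,75,TT1,positive
TT1-11,NeoBase2,0.60,0.99,112,43,TT1,positive
TT1-12,NeoBase2,0.60,2.92,422,30,TT1,positive
TT1-13,NeoBase2,0.60,2.03,465,87,TT1,positive
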