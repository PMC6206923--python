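label,coverage_pct,cost_million,hly_undiscounted,acer,icer
CVC_C1a,50,146,5215136,28,28
CVC_C1a,80,190,6773262,28,28
CVC_C1e,80,1163,30421065,38,41
BRC_C2a,95,157,1389662,113,113
CVC_C1e,95,1362,31554286,43,175
CRC_C3a,95,136,626379,217,217
BRC_C2b,95,1307,2697617,485,485
BRC_C2c,95,171,56749,3009,3009
CVC_C1i,95,161,48488,3316,3316
CRC_C3b,95,113,5602,20117,20117
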