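label,coverage_pct,cost_million,hly_undiscounted,acer,icer
CVC_C1e,50,396,4541842,87,87
CRC_C3a,95,207,870417,238,238
BRC_C2a,95,206,816200,252,252
CVC_C1e,80,549,5106391,108,272
CVC_C1e,95,626,5262580,119,491
BRC_C2b,95,1056,1627782,649,1048
BRC_C2c,95,193,22877,8434,8434
CRC_C3b,95,158,5944,26571,26571
CVC_C1i,95,156,5262,29704,29704
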