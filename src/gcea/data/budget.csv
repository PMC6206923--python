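region,quantity,value
SEA,cost_cervical,781881006
SEA,cost_breast,1454645503
SEA,cost_colorectal,364949796
SEA,total_cost,2601476305
SEA,total_hly_undiscounted,8611060
SEA,total_hly_discounted,1830047
SEA,acer,302.11
SEA,share_cervical_pct,30
SEA,share_breast_pct,56
SEA,share_colorectal_pct,14
ESSA,cost_cervical,1522549019
ESSA,cost_breast,1635269849
ESSA,cost_colorectal,248737875
ESSA,total_cost,3406556743
ESSA,total_hly_undiscounted,36378783
ESSA,total_hly_discounted,4938728
ESSA,acer,93.64
ESSA,share_cervical_pct,45
ESSA,share_breast_pct,48
ESSA,share_colorectal_pct,7
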