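cohort,marker,compartment,mean_count,se_count,n
LS_MMRD,CD3,CT,590,53,25
LS_MMRD,CD3,IM,386,52,20
SPORADIC_MMRD,CD3,CT,617,59,33
SPORADIC_MMRD,CD3,IM,241,39,21
MMRP,CD3,CT,380,40,35
MMRP,CD3,IM,157,32,25
LS_MMRD,CD8,CT,291,33,25
LS_MMRD,CD8,IM,287,45,20
SPORADIC_MMRD,CD8,CT,233,22,33
SPORADIC_MMRD,CD8,IM,116,20,21
MMRP,CD8,CT,140,18,35
MMRP,CD8,IM,80,17,25
LS_MMRD,CD45RO,CT,597,82,25
LS_MMRD,CD45RO,IM,548,81,20
SPORADIC_MMRD,CD45RO,CT,653,83,33
SPORADIC_MMRD,CD45RO,IM,296,52,21
MMRP,CD45RO,CT,450,41,35
MMRP,CD45RO,IM,236,47,25
LS_MMRD,FOXP3,CT,72,8,25
LS_MMRD,FOXP3,IM,61,12,20
SPORADIC_MMRD,FOXP3,CT,58,7,33
SPORADIC_MMRD,FOXP3,IM,28,4,21
MMRP,FOXP3,CT,46,9,35
MMRP,FOXP3,IM,23,6,25
LS_MMRD,PD1,CT,156,18,25
LS_MMRD,PD1,IM,118,20,20
SPORADIC_MMRD,PD1,CT,108,13,33
SPORADIC_MMRD,PD1,IM,49,10,21
MMRP,PD1,CT,83,13,35
MMRP,PD1,IM,42,10,25
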