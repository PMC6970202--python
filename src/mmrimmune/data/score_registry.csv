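score_id,resolution,populations
I1,BINARY,CD3_CT;CD8_CT
I2,BINARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM
I3,BINARY,CD3_CT;CD8_CT;CD45RO_CT
I4,BINARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;CD45RO_CT;CD45RO_IM
I5,BINARY,CD3_CT;CD8_CT;PD1_CT
I6,BINARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;PD1_CT;PD1_IM
I7,BINARY,CD3_CT;CD8_CT;CD45RO_CT;PD1_CT
I8,BINARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;CD45RO_CT;CD45RO_IM;PD1_CT;PD1_IM
I9,BINARY,CD3_CT;CD8_CT;CD45RO_CT;PD1_CT;FOXP3_CT
I10,BINARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;CD45RO_CT;CD45RO_IM;PD1_CT;PD1_IM;FOXP3_CT;FOXP3_IM
Q1,QUATERNARY,CD3_CT;CD8_CT
Q2,QUATERNARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM
Q3,QUATERNARY,CD3_CT;CD8_CT;CD45RO_CT
Q4,QUATERNARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;CD45RO_CT;CD45RO_IM
Q5,QUATERNARY,CD3_CT;CD8_CT;PD1_CT
Q6,QUATERNARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;PD1_CT;PD1_IM
Q7,QUATERNARY,CD3_CT;CD8_CT;CD45RO_CT;PD1_CT
Q8,QUATERNARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;CD45RO_CT;CD45RO_IM;PD1_CT;PD1_IM
Q9,QUATERNARY,CD3_CT;CD8_CT;CD45RO_CT;PD1_CT;FOXP3_CT
Q10,QUATERNARY,CD3_CT;CD3_IM;CD8_CT;CD8_IM;CD45RO_CT;CD45RO_IM;PD1_CT;PD1_IM;FOXP3_CT;FOXP3_IM
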