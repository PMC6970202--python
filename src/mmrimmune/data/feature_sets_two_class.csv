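name,columns
CD8_CT,CD8_CT
CD3_CT,CD3_CT
CD8_IM,CD8_IM
CD3_IM,CD3_IM
CD3_CT+CD3_IM,CD3_CT;CD3_IM
CD8_CT+CD8_IM,CD8_CT;CD8_IM
CD3_CT+CD8_CT,CD3_CT;CD8_CT
CD3_CT+CD8_CT+CD8_IM,CD3_CT;CD8_CT;CD8_IM
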