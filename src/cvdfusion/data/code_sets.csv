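set_name,start,end
cvd,I00,I45
cvd,I47,I99
obesity_marker,E10,E14
obesity_marker,N18,N18
obesity_marker,E65,E66
obesity_marker,E78,E78
obesity_marker,I10,I15
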