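treatment	gof_count	xcorr_count
T	3787	12946
DT	4700	106989
DAT	12402	83098
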