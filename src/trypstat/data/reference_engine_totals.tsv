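engine	msms_count	score_accepted
GOF	5410083	143062
XCORR	5410083	418768
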