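treatment	ms_runs	msms_count	matched_distinct_spectra	bfps	noise_corrected	random_corrected	score_accepted	symbols_n_ge_1
DAT	91	1829266	65894	65894	65182	54555	54555	11390
DT	91	1908258	39704	39704	39358	32360	32360	9265
T	91	1672559	65848	65848	65269	56147	56147	12137
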