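run	sample	g1c_gbp_printed	n_reads	target_coverage
parents	IntX	3.686	1622720	0.066
parents	PreX	3.531	1544840	0.066
natural	PalA	5.543	2438920	0.066
natural	PalF	5.664	2492160	0.066
natural	PicF	5.580	2455200	0.066
natural	PicB	5.212	2293280	0.066
synthetic	Hyb2	3.600	1920000	0.080
synthetic	Hyb3	3.600	1920000	0.080
synthetic	Hyb4	3.590	1914668	0.080
synthetic	IntA	3.686	1968000	0.080
synthetic	PreC	3.511	1872000	0.080
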