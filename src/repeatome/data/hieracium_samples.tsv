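id	species	ploidy	size_2C_pg	g1c_gbp_printed	analyzed_reads	coverage_printed	role	dosage_A	dosage_B
IntA	H. intybaceum	2	7.540	3.686	4349101	0.18	parent		
IntC	H. intybaceum	2	7.590	3.711	4270305	0.17	parent		
PreA	H. prenanthoides	2	7.220	3.531	4212792	0.18	parent		
PreC	H. prenanthoides	2	7.180	3.511	4368530	0.19	parent		
PalA	H. pallidiflorum	3	11.334	5.543	4278270	0.12	natural_hybrid	2	1
PalF	H. pallidiflorum	3	11.584	5.664	4467725	0.12	natural_hybrid	2	1
PicF	H. picroides	3	11.412	5.580	3767752	0.10	natural_hybrid	1	2
PicB	H. picroides	3	10.659	5.212	4338941	0.12	natural_hybrid	1	2
Hyb2	F1 synthetic	2	7.360	3.600	4457370	0.20	synthetic_hybrid	1	1
Hyb3	F1 synthetic	2	7.360	3.600	4636407	0.20	synthetic_hybrid	1	1
Hyb4	F1 synthetic	2	7.341	3.590	4465263	0.19	synthetic_hybrid	1	1
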