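species	member	phaA_bktB	fabG	fadB	hbd	phaB	phaC	phaY_e	phaZ_e	phaZ_i	bdh	aacS	scoAB	footnotes
Bacillus sp. NTK034	1	✓	✓	✓	✓	-	✓	-	-	-	✓	-	✓
Bacillus oceanisediminis 2691	0	✓	✓	✓	✓	-	✓	-	-	-	✓	-	✓
Bacillus oceanisediminis H2	0	✓	✓	✓	✓	-	✓	-	-	-	✓	-	✓
Bacillus infantis NRRL B-14911	0	✓	✓	✓	✓	-	✓	-	✓	✓	✓	-	✓
Bacillus firmus NCTC 10335	0	✓	✓	✓	✓	-	✓	-	-	-	✓	-	✓
Bacillus vietnamensis NBRC 101237	0	✓	✓	✓	✓	-	✓	-	-	✓	✓	-	✓
Bacillus vietnamensis 151-6	0	✓	✓	✓	✓	-	✓	-	-	✓	✓	-	✓
Bacillus sp. NTK074B	1	✓	✓	✓	✓	-	✓	-	-	-	✓	-	✓
Bacillus aquimaris TF-12	0	✓	✓	✓	✓	-	-	-	-	✓	✓	-	✓
Bacillus marisflavi TF-11	0	✓	✓	✓	✓	-	✓	-	-	-	✓	-	✓
Bacillus sp. NTK071	1	✓	✓	✓	✓	-	-	-	-	-	✓	-	✓
Bacillus hwajinpoensis Y2	0	✓	✓	✓	✓	-	-	-	-	-	✓	-	✓
Anaerobacillus macyae DSM 16346	0	✓	✓	✓	✓	-	-	-	✓	✓	✓	-	✓
Bacillus sp. N1-1	0	✓	✓	✓	✓	-	-	-	-	-	✓	-	✓
Bacillus hwajinpoensis 22506_14_FS	0	✓	✓	✓	✓	-	-	-	-	-	✓	-	✓
Rhodobacter sphaeroides 2.4.1	0	✓	✓	✓	✓	✓	✓	-	✓	✓	✓	-	✓	phaZ_e:no_signal_peptide
Defluviimonas alba cai42	0	✓	✓	✓	✓	✓	✓	-	-	✓	✓	-	✓
Roseicitreum antarcticum ZS2-28	0	✓	✓	✓	✓	✓	✓	-	-	✓	✓	-	✓
Rhodobacter sp. NTK016B	1	✓	✓	✓	✓	✓	✓	-	-	✓	✓	✓	✓
Pararhodobacter sp. CIC4N-9	0	✓	✓	✓	✓	✓	✓	-	-	✓	✓	✓	✓
Pararhodobacter sp. CCB-MM2	0	✓	✓	✓	✓	✓	✓	-	-	✓	✓	✓	✓
Vibrio furnissii ATCC 35016	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio proteolyticus NBRC 13287	1	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio tubiashii ATCC 19109	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio atypicus HHS02	0	✓	✓	✓	✓	✓	✓	-	-	-	-	✓	-
Vibrio parahaemolyticus ATCC 17802	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio diabolicus FDAARGOS_105	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio alginolyticus NBRC 15630	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio alginolyticus ATCC 33787	1	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio natriegens NBRC 15636	0	✓	✓	✓	-	✓	✓	✓	-	-	-	✓	-
Vibrio rotiferianus B64D1	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio harveyi FDAARGOS_107	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
Vibrio campbellii CAIM 519	0	✓	✓	✓	-	✓	✓	-	-	-	-	✓	-
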