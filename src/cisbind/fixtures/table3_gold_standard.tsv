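motif_group	flagged	screened_seq	mutated_seq	tf_gene_id	family	tf_name
I		AACGTGGG	AACCTCGG	AT3G09370	3R-MYB	MYB3R3
I		AACGTGGG	AACCTCGG	AT5G43650	bHLH	bHLH92
I		AACGTGGG	AACCTCGG	AT4G32890	GATA	GATA9
I		AACGTGGG	AACCTCGG	AT5G51870	MADS	AGL71
I		AACGTGGG	AACCTCGG	AT3G12910	NAC
I		GCACGTGGAG	GCAGCTGGAG	AT1G59640	bHLH	bHLH031, ZCW32
I		GCACGTGGAG	GCAGCTGGAG	AT2G42300	bHLH	bHLH048
I		GCACGTGGAG	GCAGCTGGAG	AT2G18300	bHLH	bHLH064, HBI1
I		GCACGTGGAG	GCAGCTGGAG	AT5G61270	bHLH	bHLH072, PIF7
I		GCACGTGGAG	GCAGCTGGAG	AT1G10120	bHLH	bHLH074
I		GCACGTGGAG	GCAGCTGGAG	AT5G62610	bHLH	bHLH079
I		GCACGTGGAG	GCAGCTGGAG	AT1G51070	bHLH	bHLH115
II		GCTGCCGGAGA	GCTGACTGAGA	AT2G43000	NAC	ANAC042, JUB1
II	x	GCTGCCGGAGA	GCTGACTGAGA	AT3G12910	NAC
II		GCCACGTCAGC	GCCATATCAGC	AT3G12910	NAC
III		GGTTGTGGT	GGTACTGGT	AT5G52260	R2R3-MYB	MYB019
III	x	GGTTGTGGT	GGTACTGGT	AT1G74650	R2R3-MYB	MYB031, ATY13
III		GGTTGTGGT	GGTACTGGT	AT3G48920	R2R3-MYB	MYB045
III		GGTTGTGGT	GGTACTGGT	AT5G54230	R2R3-MYB	MYB049
III		GGTTGTGGT	GGTACTGGT	AT1G57560	R2R3-MYB	MYB050
III		GGTTGTGGT	GGTACTGGT	AT1G16490	R2R3-MYB	MYB058
III		GGTTGTGGT	GGTACTGGT	AT1G08810	R2R3-MYB	MYB060
III		GGTTGTGGT	GGTACTGGT	AT1G09540	R2R3-MYB	MYB061
III		GGTTGTGGT	GGTACTGGT	AT1G56650	R2R3-MYB	MYB075, PAP1
III		GGTTGTGGT	GGTACTGGT	AT5G26660	R2R3-MYB	MYB086
III		GGTTGTGGT	GGTACTGGT	AT5G10280	R2R3-MYB	MYB092
III		GGTTGTGGT	GGTACTGGT	AT3G47600	R2R3-MYB	MYB094
III		GGTTGTGGT	GGTACTGGT	AT1G63910	R2R3-MYB	MYB103
III		GGTTGTGGT	GGTACTGGT	AT3G02940	R2R3-MYB	MYB107
III		ACCAAACAT	ACGATACAT	AT2G47190	R2R3-MYB	MYB002
III		ACCAAACAT	ACGATACAT	AT3G24310	R2R3-MYB	MYB071, MYB305
III		ACCAAACAT	ACGATACAT	AT3G06490	R2R3-MYB	MYB108, BOS1
III		ACCAAACAT	ACGATACAT	AT1G48000	R2R3-MYB	MYB112
III		CACCTAAC	CTCCTTAC	AT2G47190	R2R3-MYB	MYB002
III		CACCTAAC	CTCCTTAC	AT5G52260	R2R3-MYB	MYB019
III	x	CACCTAAC	CTCCTTAC	AT1G74650	R2R3-MYB	MYB031, ATY13
III		CACCTAAC	CTCCTTAC	AT5G54230	R2R3-MYB	MYB049
III		CACCTAAC	CTCCTTAC	AT1G57560	R2R3-MYB	MYB050
III		CACCTAAC	CTCCTTAC	AT1G16490	R2R3-MYB	MYB058
III		CACCTAAC	CTCCTTAC	AT1G08810	R2R3-MYB	MYB060
III		CACCTAAC	CTCCTTAC	AT1G09540	R2R3-MYB	MYB061
III		CACCTAAC	CTCCTTAC	AT1G56160	R2R3-MYB	MYB072
III		CACCTAAC	CTCCTTAC	AT5G26660	R2R3-MYB	MYB086
III		CACCTAAC	CTCCTTAC	AT5G10280	R2R3-MYB	MYB092
III		CACCTAAC	CTCCTTAC	AT3G47600	R2R3-MYB	MYB094
III		CACCTAAC	CTCCTTAC	AT5G62320	R2R3-MYB	MYB099
III		CACCTAAC	CTCCTTAC	AT1G63910	R2R3-MYB	MYB103
III		CACCTAAC	CTCCTTAC	AT3G02940	R2R3-MYB	MYB107
III		CACCTAAC	CTCCTTAC	AT3G06490	R2R3-MYB	MYB108, BOS1
III		TCGGACCAA	TCGGGTCAA
IV		CTCTCTCAC	CTCGCTCAC	AT2G21230	bZIP	bZIP30
IV		CTCTCTCAC	CTCGCTCAC	AT1G06850	bZIP	bZIP52
IV	x	CTCTCTCAC	CTCGCTCAC	AT3G12910	NAC
V		ATGTGATGC	ATGCAATGC	AT4G17880	bHLH	bHLH004, MYC4
V		ATGTGATGC	ATGCAATGC	AT2G42300	bHLH	bHLH048
V		ATGTGATGC	ATGCAATGC	AT2G18300	bHLH	bHLH064, HBI1
V		ATGTGATGC	ATGCAATGC	AT5G61270	bHLH	bHLH072, PIF7
V		GCATCACCC	GCATAGCCC	AT2G40970	G2-like	MYBC1
V		GCATCACCC	GCATAGCCC	AT5G15840	Zn finger	CO
VI		CCAACTAA	CCAGTTAA	AT5G52260	R2R3-MYB	MYB019
VI		CCAACTAA	CCAGTTAA	AT1G74650	R2R3-MYB	MYB031, ATY13
VI		CCAACTAA	CCAGTTAA	AT5G06100	R2R3-MYB	MYB033
VI		CCAACTAA	CCAGTTAA	AT3G48920	R2R3-MYB	MYB045
VI		CCAACTAA	CCAGTTAA	AT5G54230	R2R3-MYB	MYB049
VI		CCAACTAA	CCAGTTAA	AT1G57560	R2R3-MYB	MYB050
VI		CCAACTAA	CCAGTTAA	AT1G16490	R2R3-MYB	MYB058
VI		CCAACTAA	CCAGTTAA	AT1G08810	R2R3-MYB	MYB060
VI		CCAACTAA	CCAGTTAA	AT1G09540	R2R3-MYB	MYB061
VI		CCAACTAA	CCAGTTAA	AT4G37260	R2R3-MYB	MYB073
VI		CCAACTAA	CCAGTTAA	AT2G26960	R2R3-MYB	MYB081
VI		CCAACTAA	CCAGTTAA	AT5G26660	R2R3-MYB	MYB086
VI		CCAACTAA	CCAGTTAA	AT5G10280	R2R3-MYB	MYB092
VI		CCAACTAA	CCAGTTAA	AT3G47600	R2R3-MYB	MYB094
VI		CCAACTAA	CCAGTTAA	AT4G21440	R2R3-MYB	MYB102, AtM4
VI		CCAACTAA	CCAGTTAA	AT1G63910	R2R3-MYB	MYB103
VI		CCAACTAA	CCAGTTAA	AT5G49330	R2R3-MYB	MYB111, PFG3
VI		CAAACAAA
VII		TCTCCTCCAC	TCTCGACCAC	AT5G61270	bHLH	bHLH072, PIF7
VII		TCTCCTCCAC	TCTCGACCAC	AT2G21230	bZIP	bZIP30
VII		TCTCCTCCAC	TCTCGACCAC	AT3G12910	NAC
VII		CTTTCCCC	CTTGACCC	AT4G11680	C3HC4
VII		CTTTCCCC	CTTGACCC	AT3G12720	MYB	MYB67
VII		CTTTCCCC	CTTGACCC	AT5G43290	WRKY	WRKY49
VII		CCTCCTTCT	CCTCAGTCT
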