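seq_nr	element	motif_group	query_id	gene	position
1	AACGTGGG	I	roots6h_1	At4g22610	-491
2	GCACGTGGAG	I	shoots1hr_9	At4g15210	-312
3	GCTGCCGGAGA	II	shoots24hr_2	At4g17470	-295
4	GCCACGTCAGC	II	shoots24hr_2	At5g05250	-526
5	GGTTGTGGT	III	roots24hr_5	At1g21100	-839
6	ACCAAACAT	III	shoots0.25hr_16	At5g42760	-26
7	CACCTAAC	III	roots0.5hr_16	At2g22880	-288
8	TCGGACCAA	III	rootsshoots1hr_2	At5g20230	-638
9	CTCTCTCAC	IV	roots0.5hr_8	At5g20230	-934
10	ATGTGATGC	V	shoots6hr12hr_2	At1g52410	-15
11	GCATCACCC	V	shoots6hr12hr_3	At2g43510	-873
12	CCAACTAA	VI	shoots12hr24hr_6	At2g43510	-355
12a	CAAACAAA	VI	shoots12hr24hr_6	At3g28220	-155/-924
13	TCTCCTCCAC	VII	shoots1hr_32	At5g45340	-49
14	CTTTCCCC	VII	rootsshoots0.5hr_36	At1g76650	-9
15	CCTCCTTCT	VII	rootsshoots0.5hr_21	At1g20510	-37/-745
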