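# Empirically evaluated degenerate primer pairs from the published
# hymenopteran single-copy-gene panel. d = printed degree of degeneration
# per primer; total_d = printed pair total; Tm columns are the printed
# approximate melting-temperature ranges (C). Sequences 5'->3'.
pair_id	fwd	fwd_d	fwd_tm_min	fwd_tm_max	rev	rev_d	rev_tm_min	rev_tm_max	total_d
3683_01_A	GCYATYTTCGAYTTYGAYAG	32	46.0	56.8	AAVGTRAAKGATTCGTTGTA	12	47.5	54.4	384
4652_02_A	ATGATGTDGARTTTATMATACARAC	24	46.9	53.8	CWACRCTWATTTCTCTWTCAAC	16	47.1	51.9	384
4747_02_A	TTCTACGGBATGATCTTYAG	6	47.1	53.0	ACCTBGACATRATCTTVGGC	18	49.8	57.2	108
5119_01_A	GGDATYGTMGARGAGAGYGT	48	48.7	60.8	TYTTCATYTTRTCCATGTGYTC	16	48.9	56.5	768
5257_01_A	MACVAATAARTAYGGHTGYAGA	144	46.7	58.9	TAATTGGTCTARRTTGAARCT	8	47.0	52.7	1152
5592_01_A	AAYTRAATAAAGACTGGAAAGAAGA	4	50.3	53.8	GTYARATCCATYCCRTGATC	16	47.6	55.7	64
5768_01_A	ACDGTHAARGTDTGGAATGC	54	48.6	58.2	GCWACCCAAATRCWAGWTTG	16	48.8	55.0	864
6917_01_A	ATGCCVTTCTACACRGTCTA	6	52.8	58.0	CYTCGCTYTTCTTCTGCATRTC	8	53.5	58.9	48
7036_02_A	TTTGTCWGYGKGTGCCTTGT	8	55.4	60.1	TTCATRGTWGCTTCRGTATCNGT	32	51.2	59.2	256
7229_02_A	TGCYTGATHCTSTTCTTCGT	12	51.1	55.8	TRTGRAAYCTRTGRAAGATGCA	32	49.6	58.6	384
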