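# Universal sequencing-primer tail pairs (HOG-Seq catalog). Each tail is
# attached to the 5' end of a PCR primer to provide a sequencing-primer
# binding site. Tm values are approximate melting temperatures (C).
name	forward	tm_forward	reverse	tm_reverse
HOG-Seq-A	CAGTAGGTGCGTATGTCA	49.9	TGGTCAGTGGCTATTCGT	50.9
HOG-Seq-B	CGCTCATACACTTGGTTC	49.7	TCAGTCATCCTCACTTCG	50.3
HOG-Seq-C	ATACTAACTGGTGGAGCGAG	52.6	TCACTACATTACCGTATGAC	48.6
HOG-Seq-D	TCGGTCACATTGGGCTACT	54.5	CCTTGGGTCTTCGGCTTGA	56.5
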