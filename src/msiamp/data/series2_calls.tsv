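case	BAT25_ngs	BAT25_pcr	BAT26_ngs	BAT26_pcr	ngs_status	pcr_status
1	+	+	+	+	High	High
2	+	+	+	+	High	High
3	-	-	-	-	Stable	Stable
4	+	+	+	+	High	High
5	-	-	-	-	Stable	Low
6	-	-	-	-	Stable	Stable
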