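# Cysteine-scaffold screening lines for sea anemone toxin precursors,
# derived from SRDA("C.") conversions of mature anemone toxins, plus the
# compound cytolysin query. The two lines that proved too degenerate for
# bank screening ship disabled.
# columns: id	kind	query	enabled
motif 1	line	C1C##C6C#CC	1
motif 2	line	C1C##C9C#CC#.	1
motif 3	line	C8C#C*C3C#C.	1
motif 4	line	C8C*C#C*C3C	1
motif 5	line	C8C#C*C1C#C#.	1
motif 6	line	CC#C#CC*C1C*C.	1
motif 7	line	CC1C*C*C*C*C1C#.	1
motif 8	line	CC1C#C5C*C#.	1
motif 9	line	C6C*C*C*C6C#.	1
motif 10	line	C8C3C#C.	1
motif 11	line	C#C#C#C#C#C#C#C#.	1
motif 12	line	C6C#C#C1C*C1C	1
motif 13	line	C#C#C#C#.	1
motif 0	line	###.	0
motif 14	line	##C	0
motif K	compound	K>=6 AND C<=2	1
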