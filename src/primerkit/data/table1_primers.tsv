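# Published metazoan nuclear 18S/28S rDNA primer set (16 primer positions).
# printed_degeneracy: value as published for the primer pair.
# computed_degeneracy: product over positions of IUPAC set sizes. The two
# disagree only for 28S#1 (published 6; the product rule over D,Y,R gives 12).
name	gene	orientation	sequence	pair	printed_degeneracy	computed_degeneracy
18S#1	18S	forward	CTGGTGCCAGCAGCCGCGGYAA	18S#1	2	2
18S#2	18S	forward	AACTTAAAGRAATTGACGGA	18S#2	2	2
18S#2_RC	18S	reverse_complement	TCCGTCAATTYCTTTAAGTT	18S#2	2	2
18S#3	18S	forward	GYGGTGCATGGCCGTTSKTRGTT	18S#3	16	16
18S#3_RC	18S	reverse_complement	AACYAMSAACGGCCATGCACCRC	18S#3	16	16
18S#4	18S	forward	ATAACAGGTCWGTRATGCCCTYMG	18S#4	16	16
18S#4_RC	18S	reverse_complement	CKRAGGGCATYACWGACCTGTTAT	18S#4	16	16
18S#5_RC	18S	reverse_complement	GTGTGYACAAAGGBCAGGGAC	18S#5	6	6
28S#1	28S	forward	CCGTCTTGAAACACGGDCYRAG	28S#1	6	12
28S#2	28S	forward	AGGGGCGAAAGACYAATCGAA	28S#2	2	2
28S#2_RC	28S	reverse_complement	TTCGATTRGTCTTTCGCCCCT	28S#2	2	2
28S#3	28S	forward	TTTTGGTAAGCAGAACTGGYG	28S#3	2	2
28S#3_RC	28S	reverse_complement	CRCCAGTTCTGCTTACCAAAA	28S#3	2	2
28S#4	28S	forward	GATCTYRGTGGYAGTAGCRAVT	28S#4	48	48
28S#4_RC	28S	reverse_complement	ABTYGCTACTRCCACYRAGATC	28S#4	48	48
28S#5	28S	forward	GGGAATCYRACTGTHTAATTAAA	28S#5	12	12
28S#5_RC	28S	reverse_complement	TTTAATTADACAGTYRGATTCCC	28S#5	12	12
28S#6	28S	forward	TGATTTCTGCCCAGTGCTYWGAAWGT	28S#6	8	8
28S#6_RC	28S	reverse_complement	ACWTTCWRAGCACTGGGCAGAAATCA	28S#6	8	8
28S#7	28S	forward	AACGGCGGRRGTAACTATGACTYT	28S#7	8	8
28S#7_RC	28S	reverse_complement	ARAGTCATAGTTACYYCCGCCGTT	28S#7	8	8
28S#8	28S	forward	GGGAAAGAAGACCCTGTTGAG	28S#8	1	1
28S#8_RC	28S	reverse_complement	CTCAACAGGGTCTTCTTTCCC	28S#8	1	1
28S#9	28S	forward	AAGACCCTGTTGAGYTTGACTCT	28S#9	2	2
28S#9_RC	28S	reverse_complement	AGAGTCAARCTCAACAGGGTCTT	28S#9	2	2
28S#10	28S	forward	GGGAGTTTGRCTGGGGCGG	28S#10	2	2
28S#10_RC	28S	reverse_complement	CCGCCCCAGYCAAACTCCC	28S#10	2	2
28S#11_RC	28S	reverse_complement	GCTTGGCBGCCACAAGCCAGTTA	28S#11	3	3
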