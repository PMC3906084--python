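set_id	snpq_bin	td_bin	validated	total
set1	0	0	5	9
set1	0	1	5	13
set1	0	2	5	10
set1	0	3	4	7
set1	0	4	0	4
set1	1	0	7	8
set1	1	1	5	8
set1	1	2	4	12
set1	1	3	4	12
set1	1	4	1	5
set1	2	0	4	8
set1	2	1	10	12
set1	2	2	3	12
set1	2	3	0	9
set1	2	4	2	5
set1	3	0	7	9
set1	3	1	5	7
set1	3	2	3	9
set1	3	3	1	7
set1	3	4	0	3
set1	4	0	6	6
set1	4	1	6	9
set1	4	2	5	10
set1	4	3	4	12
set1	4	4	2	5
set1	5	0	1	1
set1	5	1	6	9
set1	5	2	6	7
set1	5	3	6	8
set1	5	4	5	6
set1	6	0	2	2
set1	6	1	7	8
set1	6	2	10	10
set1	6	3	8	10
set1	6	4	6	8
set1	7	0	2	2
set1	7	1	6	6
set1	7	2	13	13
set1	7	3	10	10
set1	7	4	6	7
set1	8	0	0	0
set1	8	1	0	0
set1	8	2	10	10
set1	8	3	9	10
set1	8	4	10	10
set2	0	0	1	2
set2	0	1	1	2
set2	0	2	0	1
set2	0	3	0	0
set2	0	4	0	0
set2	1	0	11	15
set2	1	1	7	10
set2	1	2	2	9
set2	1	3	1	6
set2	1	4	0	0
set2	2	0	7	9
set2	2	1	9	13
set2	2	2	1	6
set2	2	3	0	7
set2	2	4	0	4
set2	3	0	7	8
set2	3	1	16	17
set2	3	2	8	14
set2	3	3	3	10
set2	3	4	0	4
set2	4	0	0	0
set2	4	1	5	6
set2	4	2	6	8
set2	4	3	4	8
set2	4	4	1	10
set2	5	0	0	0
set2	5	1	8	11
set2	5	2	15	16
set2	5	3	8	13
set2	5	4	1	7
set2	6	0	0	0
set2	6	1	3	3
set2	6	2	11	11
set2	6	3	17	21
set2	6	4	2	11
set2	7	0	0	0
set2	7	1	0	0
set2	7	2	7	7
set2	7	3	14	16
set2	7	4	15	24
set2	8	0	0	0
set2	8	1	0	0
set2	8	2	0	0
set2	8	3	5	5
set2	8	4	19	22
set3	0	0	6	7
set3	0	1	7	10
set3	0	2	1	6
set3	0	3	3	8
set3	0	4	0	4
set3	1	0	5	7
set3	1	1	6	11
set3	1	2	5	13
set3	1	3	2	6
set3	1	4	0	3
set3	2	0	6	8
set3	2	1	2	4
set3	2	2	3	8
set3	2	3	3	5
set3	2	4	0	3
set3	3	0	3	6
set3	3	1	8	10
set3	3	2	3	10
set3	3	3	0	2
set3	3	4	0	2
set3	4	0	7	7
set3	4	1	8	8
set3	4	2	4	7
set3	4	3	3	8
set3	4	4	4	5
set3	5	0	2	2
set3	5	1	9	13
set3	5	2	8	9
set3	5	3	4	4
set3	5	4	1	3
set3	6	0	4	4
set3	6	1	2	3
set3	6	2	12	12
set3	6	3	9	10
set3	6	4	6	6
set3	7	0	1	1
set3	7	1	6	6
set3	7	2	12	12
set3	7	3	14	15
set3	7	4	9	10
set3	8	0	0	0
set3	8	1	0	0
set3	8	2	7	7
set3	8	3	8	9
set3	8	4	10	10
set4	0	0	1	2
set4	0	1	1	1
set4	0	2	0	2
set4	0	3	0	1
set4	0	4	0	1
set4	1	0	10	13
set4	1	1	7	10
set4	1	2	2	6
set4	1	3	1	6
set4	1	4	0	3
set4	2	0	8	10
set4	2	1	11	14
set4	2	2	2	7
set4	2	3	1	8
set4	2	4	0	6
set4	3	0	7	8
set4	3	1	14	15
set4	3	2	8	14
set4	3	3	2	11
set4	3	4	0	5
set4	4	0	0	0
set4	4	1	5	6
set4	4	2	5	6
set4	4	3	2	4
set4	4	4	1	5
set4	5	0	0	0
set4	5	1	10	13
set4	5	2	14	15
set4	5	3	10	12
set4	5	4	1	10
set4	6	0	0	0
set4	6	1	1	1
set4	6	2	12	12
set4	6	3	17	18
set4	6	4	2	8
set4	7	0	0	0
set4	7	1	0	0
set4	7	2	7	7
set4	7	3	14	16
set4	7	4	15	21
set4	8	0	0	0
set4	8	1	0	0
set4	8	2	0	0
set4	8	3	5	5
set4	8	4	19	22
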