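>Feature fixture7
177	776	gene
			gene	psbA
177	776	CDS
			gene	psbA
			transl_table	11
1203	2102	gene
			gene	rbcL
1203	2102	CDS
			gene	rbcL
			transl_table	11
3448	2699	gene
			gene	matK
3448	2699	CDS
			gene	matK
			transl_table	11
5187	4588	gene
			gene	atpA
5187	4588	CDS
			gene	atpA
			transl_table	11
5364	5813	gene
			gene	psbD
5364	5813	CDS
			gene	psbD
			transl_table	11
6227	5796	gene
			gene	psbB
6227	5796	CDS
			gene	psbB
			transl_table	11
6603	8758	gene
			gene	ndhB
6603	7322	CDS
8003	8758
			gene	ndhB
			transl_table	11
11022	9463	gene
			gene	clpP
11022	10813	CDS
10252	9962
9531	9463
			gene	clpP
			transl_table	11
11453	12800	gene
			gene	petB
11453	11458	CDS
12159	12800
			gene	petB
			transl_table	11
13276	14408	gene
			gene	petD
13276	13283	CDS
13934	14408
			gene	petD
			transl_table	11
15801	14794	gene
			gene	rpl16
15801	15793	CDS
15192	14794
			gene	rpl16
			transl_table	11
26228	24587	gene
			gene	ndhA
26228	25689	CDS
25138	24587
			gene	ndhA
			transl_table	11
26815	27414	gene
			gene	ccsA
26815	27414	CDS
			gene	ccsA
			transl_table	11
18423	19322	gene
			gene	rrn16
18423	19322	rRNA
			gene	rrn16
33578	32679	gene
			gene	rrn16
33578	32679	rRNA
			gene	rrn16
19745	21244	gene
			gene	rrn23
19745	21244	rRNA
			gene	rrn23
32256	30757	gene
			gene	rrn23
32256	30757	rRNA
			gene	rrn23
21667	21766	gene
			gene	rrn4.5
21667	21766	rRNA
			gene	rrn4.5
30334	30235	gene
			gene	rrn4.5
30334	30235	rRNA
			gene	rrn4.5
22189	22308	gene
			gene	rrn5
22189	22308	rRNA
			gene	rrn5
29812	29693	gene
			gene	rrn5
29812	29693	rRNA
			gene	rrn5
16392	23528	gene
			gene	rps12
			exception	trans-splicing
16392	16279	CDS
22731	22962
23503	23528
			gene	rps12
			transl_table	11
			exception	trans-splicing
16392	28473	gene
			gene	rps12
			exception	trans-splicing
16392	16279	CDS
29270	29039
28498	28473
			gene	rps12
			transl_table	11
			exception	trans-splicing
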