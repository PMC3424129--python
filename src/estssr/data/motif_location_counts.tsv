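group	motif	location	count
di	AT	three_prime_utr	154
di	AT	five_prime_utr	70
di	AT	coding	73
di	AT	undetermined	6
di	AG	three_prime_utr	42
di	AG	five_prime_utr	53
di	AG	coding	155
di	AG	undetermined	6
di	AC	three_prime_utr	27
di	AC	five_prime_utr	18
di	AC	coding	46
di	AC	undetermined	3
di	CG	three_prime_utr	0
di	CG	five_prime_utr	0
di	CG	coding	2
di	CG	undetermined	0
tri	AAG	three_prime_utr	19
tri	AAG	five_prime_utr	36
tri	AAG	coding	285
tri	AAG	undetermined	2
tri	ATG	three_prime_utr	19
tri	ATG	five_prime_utr	32
tri	ATG	coding	178
tri	ATG	undetermined	1
tri	AGG	three_prime_utr	7
tri	AGG	five_prime_utr	49
tri	AGG	coding	170
tri	AGG	undetermined	0
tri	AGC	three_prime_utr	18
tri	AGC	five_prime_utr	34
tri	AGC	coding	129
tri	AGC	undetermined	2
tri	AAT	three_prime_utr	55
tri	AAT	five_prime_utr	22
tri	AAT	coding	49
tri	AAT	undetermined	2
tri	ACC	three_prime_utr	6
tri	ACC	five_prime_utr	7
tri	ACC	coding	64
tri	ACC	undetermined	0
tri	GGC	three_prime_utr	9
tri	GGC	five_prime_utr	15
tri	GGC	coding	38
tri	GGC	undetermined	0
tri	AAC	three_prime_utr	11
tri	AAC	five_prime_utr	9
tri	AAC	coding	32
tri	AAC	undetermined	0
tri	ACG	three_prime_utr	0
tri	ACG	five_prime_utr	1
tri	ACG	coding	11
tri	ACG	undetermined	0
tri	AGT	three_prime_utr	2
tri	AGT	five_prime_utr	1
tri	AGT	coding	4
tri	AGT	undetermined	0
tetra	.	three_prime_utr	61
tetra	.	five_prime_utr	65
tetra	.	coding	60
tetra	.	undetermined	8
penta	.	three_prime_utr	180
penta	.	five_prime_utr	193
penta	.	coding	349
penta	.	undetermined	19
hexa	.	three_prime_utr	154
hexa	.	five_prime_utr	225
hexa	.	coding	703
hexa	.	undetermined	12
compound	.	three_prime_utr	15
compound	.	five_prime_utr	5
compound	.	coding	35
compound	.	undetermined	1
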