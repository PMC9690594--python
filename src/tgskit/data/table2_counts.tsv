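group	gene	rs_id	genotype	count
controls	ACE	rs4341	DD	49
controls	ACE	rs4341	ID	200
controls	ACE	rs4341	II	167
controls	ACTN3	rs1815739	RR	84
controls	ACTN3	rs1815739	RX	226
controls	ACTN3	rs1815739	XX	106
controls	ALDH2	rs671	GG	232
controls	ALDH2	rs671	GA	149
controls	ALDH2	rs671	AA	35
controls	CHRNB3	rs4950	AA	323
controls	CHRNB3	rs4950	GA	77
controls	CHRNB3	rs4950	GG	16
controls	CKM	rs8111989	AA	308
controls	CKM	rs8111989	GA	98
controls	CKM	rs8111989	GG	10
controls	CNTFR	rs41274853	CC	210
controls	CNTFR	rs41274853	CT	170
controls	CNTFR	rs41274853	TT	36
controls	FTO	rs9939609	TT	269
controls	FTO	rs9939609	TA	130
controls	FTO	rs9939609	AA	17
controls	GALNTL6	rs558129	CC	304
controls	GALNTL6	rs558129	CT	101
controls	GALNTL6	rs558129	TT	11
controls	IGF2	rs680	CC	143
controls	IGF2	rs680	CT	193
controls	IGF2	rs680	TT	80
controls	MCT1	rs1049434	AA	199
controls	MCT1	rs1049434	TA	175
controls	MCT1	rs1049434	TT	42
controls	PPARGC1A	rs8192678	AA	79
controls	PPARGC1A	rs8192678	GA	184
controls	PPARGC1A	rs8192678	GG	153
controls	TRHR	rs7832552	TT	129
controls	TRHR	rs7832552	CT	175
controls	TRHR	rs7832552	CC	112
all_weightlifters	ACE	rs4341	DD	40
all_weightlifters	ACE	rs4341	ID	79
all_weightlifters	ACE	rs4341	II	73
all_weightlifters	ACTN3	rs1815739	RR	49
all_weightlifters	ACTN3	rs1815739	RX	86
all_weightlifters	ACTN3	rs1815739	XX	57
all_weightlifters	ALDH2	rs671	GG	99
all_weightlifters	ALDH2	rs671	GA	76
all_weightlifters	ALDH2	rs671	AA	17
all_weightlifters	CHRNB3	rs4950	AA	127
all_weightlifters	CHRNB3	rs4950	GA	61
all_weightlifters	CHRNB3	rs4950	GG	4
all_weightlifters	CKM	rs8111989	AA	152
all_weightlifters	CKM	rs8111989	GA	34
all_weightlifters	CKM	rs8111989	GG	6
all_weightlifters	CNTFR	rs41274853	CC	104
all_weightlifters	CNTFR	rs41274853	CT	64
all_weightlifters	CNTFR	rs41274853	TT	24
all_weightlifters	FTO	rs9939609	TT	118
all_weightlifters	FTO	rs9939609	TA	65
all_weightlifters	FTO	rs9939609	AA	9
all_weightlifters	GALNTL6	rs558129	CC	137
all_weightlifters	GALNTL6	rs558129	CT	49
all_weightlifters	GALNTL6	rs558129	TT	6
all_weightlifters	IGF2	rs680	CC	80
all_weightlifters	IGF2	rs680	CT	83
all_weightlifters	IGF2	rs680	TT	29
all_weightlifters	MCT1	rs1049434	AA	75
all_weightlifters	MCT1	rs1049434	TA	91
all_weightlifters	MCT1	rs1049434	TT	26
all_weightlifters	PPARGC1A	rs8192678	AA	35
all_weightlifters	PPARGC1A	rs8192678	GA	102
all_weightlifters	PPARGC1A	rs8192678	GG	55
all_weightlifters	TRHR	rs7832552	TT	52
all_weightlifters	TRHR	rs7832552	CT	98
all_weightlifters	TRHR	rs7832552	CC	42
international	ACE	rs4341	DD	12
international	ACE	rs4341	ID	22
international	ACE	rs4341	II	33
international	ACTN3	rs1815739	RR	21
international	ACTN3	rs1815739	RX	31
international	ACTN3	rs1815739	XX	15
international	ALDH2	rs671	GG	34
international	ALDH2	rs671	GA	26
international	ALDH2	rs671	AA	7
international	CHRNB3	rs4950	AA	47
international	CHRNB3	rs4950	GA	19
international	CHRNB3	rs4950	GG	1
international	CKM	rs8111989	AA	52
international	CKM	rs8111989	GA	13
international	CKM	rs8111989	GG	2
international	CNTFR	rs41274853	CC	26
international	CNTFR	rs41274853	CT	28
international	CNTFR	rs41274853	TT	13
international	FTO	rs9939609	TT	44
international	FTO	rs9939609	TA	21
international	FTO	rs9939609	AA	2
international	GALNTL6	rs558129	CC	48
international	GALNTL6	rs558129	CT	17
international	GALNTL6	rs558129	TT	2
international	IGF2	rs680	CC	25
international	IGF2	rs680	CT	32
international	IGF2	rs680	TT	10
international	MCT1	rs1049434	AA	28
international	MCT1	rs1049434	TA	30
international	MCT1	rs1049434	TT	9
international	PPARGC1A	rs8192678	AA	13
international	PPARGC1A	rs8192678	GA	38
international	PPARGC1A	rs8192678	GG	16
international	TRHR	rs7832552	TT	13
international	TRHR	rs7832552	CT	32
international	TRHR	rs7832552	CC	22
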