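parcel	hemisphere	wholebrain_index
8BM	left	62
d32	left	61
8BM	right	242
d32	right	241
8C	left	72
9-46d	left	85
a9-46v	left	84
p9-46v	left	82
i6-8	left	96
s6-8	left	97
46	left	83
8C	right	252
9-46d	right	265
a9-46v	right	264
p9-46v	right	262
i6-8	right	276
s6-8	right	277
46	right	263
IFJp	left	79
44	left	73
p47r	left	170
IFJp	right	259
44	right	253
p47r	right	350
PF	left	147
PFm	left	148
IP2	left	143
IP1	left	144
PGs	left	150
PF	right	327
PFm	right	328
IP2	right	323
IP1	right	324
PGs	right	330
FOP4	left	107
FOP5	left	168
AVI	left	110
FOP4	right	287
FOP5	right	348
AVI	right	290
p10p	left	169
a10p	left	88
11l	left	90
p10p	right	349
a10p	right	268
11l	right	270
POS2	left	14
7m	left	29
POS2	right	194
7m	right	209
6a	left	95
FEF	left	9
55b	left	11
6r	left	77
6a	right	275
FEF	right	189
55b	right	191
6r	right	257
AIP	left	116
LIPd	left	94
7PL	left	45
7Am	left	44
7Pm	left	28
MIP	left	49
AIP	right	296
LIPd	right	274
7PL	right	225
7Am	right	224
7Pm	right	208
MIP	right	229
caudate	left	362
caudate	right	371
putamen	left	366
putamen	right	375
thalamus	left	367
thalamus	right	376
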