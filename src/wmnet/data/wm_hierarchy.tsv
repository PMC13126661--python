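parcel	hemisphere	kind	group
8BM	left	cortical	ACMPC
d32	left	cortical	ACMPC
8BM	right	cortical	ACMPC
d32	right	cortical	ACMPC
8C	left	cortical	DLPC
9-46d	left	cortical	DLPC
a9-46v	left	cortical	DLPC
p9-46v	left	cortical	DLPC
i6-8	left	cortical	DLPC
s6-8	left	cortical	DLPC
46	left	cortical	DLPC
8C	right	cortical	DLPC
9-46d	right	cortical	DLPC
a9-46v	right	cortical	DLPC
p9-46v	right	cortical	DLPC
i6-8	right	cortical	DLPC
s6-8	right	cortical	DLPC
46	right	cortical	DLPC
IFJp	left	cortical	IFC
44	left	cortical	IFC
p47r	left	cortical	IFC
IFJp	right	cortical	IFC
44	right	cortical	IFC
p47r	right	cortical	IFC
PF	left	cortical	IPC
PFm	left	cortical	IPC
IP2	left	cortical	IPC
IP1	left	cortical	IPC
PGs	left	cortical	IPC
PF	right	cortical	IPC
PFm	right	cortical	IPC
IP2	right	cortical	IPC
IP1	right	cortical	IPC
PGs	right	cortical	IPC
FOP4	left	cortical	IFOC
FOP5	left	cortical	IFOC
AVI	left	cortical	IFOC
FOP4	right	cortical	IFOC
FOP5	right	cortical	IFOC
AVI	right	cortical	IFOC
p10p	left	cortical	OPFC
a10p	left	cortical	OPFC
11l	left	cortical	OPFC
p10p	right	cortical	OPFC
a10p	right	cortical	OPFC
11l	right	cortical	OPFC
POS2	left	cortical	PCC
7m	left	cortical	PCC
POS2	right	cortical	PCC
7m	right	cortical	PCC
6a	left	cortical	PMC
FEF	left	cortical	PMC
55b	left	cortical	PMC
6r	left	cortical	PMC
6a	right	cortical	PMC
FEF	right	cortical	PMC
55b	right	cortical	PMC
6r	right	cortical	PMC
AIP	left	cortical	SPC
LIPd	left	cortical	SPC
7PL	left	cortical	SPC
7Am	left	cortical	SPC
7Pm	left	cortical	SPC
MIP	left	cortical	SPC
AIP	right	cortical	SPC
LIPd	right	cortical	SPC
7PL	right	cortical	SPC
7Am	right	cortical	SPC
7Pm	right	cortical	SPC
MIP	right	cortical	SPC
caudate	left	subcortical	caudate
caudate	right	subcortical	caudate
putamen	left	subcortical	putamen
putamen	right	subcortical	putamen
thalamus	left	subcortical	thalamus
thalamus	right	subcortical	thalamus
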