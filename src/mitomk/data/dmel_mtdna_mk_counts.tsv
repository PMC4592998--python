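gene	PN	PS	DN	DS
ATPase6	5	2	11	35
ATPase8	1	0	2	8
COI	0	16	8	101
COII	1	5	6	39
COIII	1	9	8.5	47.5
Cyt-b	2	5	17.5	67.5
ND1	3	3	11	45
ND2	6	5	25	41
ND3	1	1	5	22
ND4	7	7	24	63
ND4L	2	1	1	7
ND5	4	10	55.833	107.167
ND6	2	4	21.5	22.5
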