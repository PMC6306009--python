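id	n	d	oh_positions	epoxy_spans	carboxyls
16:0	16	0			1
16-hydroxy-16:0	16	0	16		1
2-hydroxy-16:0	16	0	2		1
10,16-dihydroxy-16:0	16	0	10,16		1
10,16-dihydroxy-16:1	16	1	10,16		1
16:0-diacid	16	0			1,16
18:0	18	0			1
18:1	18	1			1
18:2	18	2			1
18-hydroxy-18:1	18	1	18		1
18-hydroxy-18:2	18	2	18		1
18-hydroxy-18:3	18	3	18		1
9,10,18-trihydroxy-18:0	18	0	9,10,18		1
9,10,18-trihydroxy-18:1	18	1	9,10,18		1
9,10,18-trihydroxy-18:2	18	2	9,10,18		1
9,10,18-trihydroxy-18:3	18	3	9,10,18		1
9,10-dihydroxy-18:0-diacid	18	0	9,10		1,18
18-hydroxy-9,10-epoxy-18:0	18	0	18	9-10	1
18-hydroxy-9,10-epoxy-18:1	18	1	18	9-10	1
18-hydroxy-9,10-epoxy-18:2	18	2	18	9-10	1
20:0	20	0			1
20:3	20	3			1
2-hydroxy-22:0	22	0	2		1
2-hydroxy-24:0	24	0	2		1
30:0	30	0			1
26:0-ol	26	0	1		
28:0-ol	28	0	1		
30:0-ol	30	0	1		
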