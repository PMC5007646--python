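# toy interaction network: two triangles bridged by a hub (10 rows,
# 2 duplicate pairs -> 8 unique edges)
A1	A2	0.95
A1	A3	0.95
A2	A3	0.95
A1	A2	0.95
B1	B2	0.95
B1	B3	0.95
B2	B3	0.95
B1	B2	0.95
HUB	A1	0.95
HUB	B1	0.95
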