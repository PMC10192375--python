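gene_name	chain	segment_type	anchor_offset	frame_offset
TRBV15-1	beta	V	210	0
TRBV19	beta	V	210	0
TRBV28	beta	V	210	0
TRBV6-5	beta	V	210	0
TRAV12-1	alpha	V	210	0
TRAV19	alpha	V	210	0
TRAV29	alpha	V	210	0
TRAV8-2	alpha	V	210	0
TRBJ1-1	beta	J	21	0
TRBJ2-3	beta	J	21	0
TRBJ2-7	beta	J	21	0
TRAJ33	alpha	J	21	0
TRAJ42	alpha	J	21	0
TRAJ49	alpha	J	21	0
TRBD1	beta	D		0
TRBC1	beta	C		0
TRAC	alpha	C		0
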