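# Photonuclear activation products relevant to tissue imaged after
# high-energy (>15 MeV) photon irradiation.
# symbol	half_life_min	parent_element	reaction
C11	20.39	C	(g,n)
O15	2.04	O	(g,n)
N13	9.97	N	(g,n)
P30	2.5	P	(g,n)
Ca39	0.014333333333333333	Ca	(g,n)
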