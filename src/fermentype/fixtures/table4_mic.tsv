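strain_id	species	fluconazole	clotrimazole	amphotericin_b
BL3	Kluyveromyces marxianus	4	0.12	2
BL8	Kluyveromyces marxianus	8	0.5	8
DL4	Kluyveromyces marxianus	8	0.5	32*
TJY52	Kluyveromyces marxianus	8	0.03**	4
CL1	Pichia fermentans	64	0.03**	8
BL2	Pichia fermentans	128*	0.03**	16
CL2	Saccharomyces cerevisiae	16	0.03**	2
BL9	Saccharomyces cerevisiae	16	0.5	2
TJY51	Kazachstania unispora	128*	0.25	4
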