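species	strain_id	haeiii	hinfi
Kluyveromyces marxianus	AL1	655,80	240,185,140,80
Kluyveromyces marxianus	AL2	655,80	240,185,120,80
Kluyveromyces marxianus	AL3	655,80	240,185,120,80
Kluyveromyces marxianus	AL4	655,80	240,185,120,80
Kluyveromyces marxianus	AL5	655,80	240,185,140,80
Kluyveromyces marxianus	BL1	655,80	240,185,120,80
Kluyveromyces marxianus	BL3	655,80	240,185,120,80
Kluyveromyces marxianus	BL4	655,80	240,185,140,80
Kluyveromyces marxianus	BL5	655,80	240,185,120,80
Kluyveromyces marxianus	BL6	655,80	240,185,140,80
Kluyveromyces marxianus	BL7	655,80	240,185,140,80
Kluyveromyces marxianus	BL8	655,80	240,185,120,80
Kluyveromyces marxianus	BL12	655,80	240,185,140,80
Kluyveromyces marxianus	BL13	655,80	240,185,140,80
Kluyveromyces marxianus	BL14	655,80	240,185,140,80
Kluyveromyces marxianus	CL5	655,80	240,185,120,80
Kluyveromyces marxianus	CL6	655,80	240,185,140,80
Kluyveromyces marxianus	DL2	655,80	240,185,140,80
Kluyveromyces marxianus	DL4	655,80	240,185,140,80
Kluyveromyces marxianus	DL5	655,80	240,185,140,80
Kluyveromyces marxianus	DL6	655,80	240,185,140,80
Kluyveromyces marxianus	DL10a	655,80	240,185,140,80
Kluyveromyces marxianus	DL10b	655,80	240,185,140,80
Kluyveromyces marxianus	DL11	655,80	240,185,140,80
Kluyveromyces marxianus	DL12	655,80	240,185,140,80
Kluyveromyces marxianus	TJY52	655,80	240,185,120,80
Kluyveromyces marxianus	TJY54	655,80	240,185,120,80
Kluyveromyces marxianus	TJY59	655,80	240,185,120,80
Kluyveromyces marxianus	TJY60	655,80	240,185,120,80
Saccharomyces cerevisiae	BL9	320,230,180,150	365,155
Saccharomyces cerevisiae	BL10	320,230,180,150	365,155
Saccharomyces cerevisiae	BL11	320,230,180,150	365,155
Saccharomyces cerevisiae	CL2	320,230,180,150	365,155
Saccharomyces cerevisiae	CL3	320,230,180,150	365,155
Saccharomyces cerevisiae	CL4	320,230,180,150	365,155
Saccharomyces cerevisiae	DL3	320,230,180,150	365,155
Saccharomyces cerevisiae	DL7	320,230,180,150	365,155
Saccharomyces cerevisiae	TJY58	320,230,180,150	365,155
Saccharomyces cerevisiae	TJY61	320,230,180,150	365,155
Pichia fermentans	BL2	340,80	250,200
Pichia fermentans	CL1	340,80	250,200
Pichia fermentans	CL7	340,80	250,200
Pichia fermentans	DL1	340,80	250,200
Pichia fermentans	DL8a	340,80	250,200
Pichia fermentans	DL8b	340,80	250,200
Pichia fermentans	DL9	340,80	250,200
Pichia fermentans	TJY50	340,80	250,200
Pichia fermentans	TJY53	340,80	250,200
Pichia fermentans	TJY55	340,80	250,200
Pichia fermentans	TJY56	340,80	250,200
Pichia fermentans	TJY57	340,80	250,200
Kazachstania unispora	TJY51	550,150	370
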