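species	strain_id	h2o2_mm	invasive	hyphae_ypd27	hyphae_ypd37	hyphae_ynb27	hyphae_ynb37	hyphae_rpmi37
Kluyveromyces marxianus	AL1	4	0	-	-	-	-	-
Kluyveromyces marxianus	AL2	9	0	-	-	-	-	-
Kluyveromyces marxianus	AL3	11	0	-	-	-	-	-
Kluyveromyces marxianus	AL4	4	0	-	-	-	-	-
Kluyveromyces marxianus	AL5	11	0	-	-	-	-	-
Kluyveromyces marxianus	BL1	10	1	-	-	-	-	-
Kluyveromyces marxianus	BL3	10	1	+	+	+	-	+
Kluyveromyces marxianus	BL4	14	0	-	-	-	+	-
Kluyveromyces marxianus	BL5	9	1	+	-	+	+	-
Kluyveromyces marxianus	BL6	10	0	-	+	-	-	-
Kluyveromyces marxianus	BL7	11	0	-	-	-	-	-
Kluyveromyces marxianus	BL8	11	0	-	-	-	-	-
Kluyveromyces marxianus	BL12	10	0	-	-	-	-	-
Kluyveromyces marxianus	BL13	12	0	-	-	-	-	-
Kluyveromyces marxianus	BL14	13	3	-	-	-	-	-
Kluyveromyces marxianus	CL5	4	2	+	+	+	+	+
Kluyveromyces marxianus	CL6	13	0	-	-	-	-	-
Kluyveromyces marxianus	DL2	13	0	-	-	-	-	-
Kluyveromyces marxianus	DL4	12	2b	-	-	-	-	-
Kluyveromyces marxianus	DL5	11	0	-	-	-	-	-
Kluyveromyces marxianus	DL6	12	0	-	-	-	-	-
Kluyveromyces marxianus	DL10a	11	0	-	-	-	-	-
Kluyveromyces marxianus	DL10b	13	0	-	-	-	-	-
Kluyveromyces marxianus	DL11	13	1	-	-	-	-	-
Kluyveromyces marxianus	DL12	10	0	-	-	-	-	-
Kluyveromyces marxianus	TJY52	9	1	+	+	+	+	-
Kluyveromyces marxianus	TJY54	9	1	+	+	+	+	+
Kluyveromyces marxianus	TJY59	9	1	+	+	+	+	-
Kluyveromyces marxianus	TJY60	10	1	+	+	+	+	+
Saccharomyces cerevisiae	BL9	17	3	+	-	+	-	+
Saccharomyces cerevisiae	BL10	16	3	-	-	-	-	-
Saccharomyces cerevisiae	BL11	9	0	-	-	-	-	-
Saccharomyces cerevisiae	CL2	5	0	-	-	-	-	-
Saccharomyces cerevisiae	CL3	14	0	-	-	-	-	-
Saccharomyces cerevisiae	CL4	13	0	+	+	+	-	-
Saccharomyces cerevisiae	DL3	17	0	-	+	-	+	+
Saccharomyces cerevisiae	DL7	15	3b	-	-	-	-	-
Saccharomyces cerevisiae	TJY58	16	0	+	-	+	-	+
Saccharomyces cerevisiae	TJY61	12	0	-	-	-	-	-
Pichia fermentans	BL2	11	2	+	+	+	-	+
Pichia fermentans	CL1	13	3	+	+	+	+	+
Pichia fermentans	CL7	11	1	-	-	-	-	-
Pichia fermentans	DL1	14	3	-	+	-	-	-
Pichia fermentans	DL8a	13	0	-	-	-	-	-
Pichia fermentans	DL8b	14	0	-	-	-	-	-
Pichia fermentans	DL9	15	1	-	-	-	-	-
Pichia fermentans	TJY50	9	1	-	-	-	-	-
Pichia fermentans	TJY53	14	1	-	-	-	-	-
Pichia fermentans	TJY55	13	1	-	-	-	-	-
Pichia fermentans	TJY56	13	1	+	+	+	+	+
Pichia fermentans	TJY57	14	1	-	-	-	-	-
Kazachstania unispora	TJY51	12	0	-	n.d.	-	n.d.	n.d.
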