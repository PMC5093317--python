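strain_id	species	isolation_medium	sample_origin	accession
AL1	Kluyveromyces marxianus	M17	original	KX905245
AL2	Kluyveromyces marxianus	M17	original	KX905246
AL3	Kluyveromyces marxianus	M17	original	KX905247
AL4	Kluyveromyces marxianus	M17	original	KX905248
AL5	Kluyveromyces marxianus	M17	original	KX905249
BL1	Kluyveromyces marxianus	YPD	original	KX905250
BL3	Kluyveromyces marxianus	WL	original	KX905251
BL4	Kluyveromyces marxianus	WL	original	KX905252
BL5	Kluyveromyces marxianus	WL	original	KX905253
BL6	Kluyveromyces marxianus	WL	original	KX905254
BL7	Kluyveromyces marxianus	WL	original	KX905255
BL8	Kluyveromyces marxianus	WL	original	KX905256
BL12	Kluyveromyces marxianus	WL	original	KX905257
BL13	Kluyveromyces marxianus	WL	original	KX905258
BL14	Kluyveromyces marxianus	WL	original	KX905259
CL5	Kluyveromyces marxianus	MRS	original	KX905260
CL6	Kluyveromyces marxianus	MRS	original	KX905261
DL2	Kluyveromyces marxianus	MRS pH 5.4	original	KX905262
DL4	Kluyveromyces marxianus	MRS pH 5.4	original	KX905263
DL5	Kluyveromyces marxianus	MRS pH 5.4	original	KX905264
DL6	Kluyveromyces marxianus	MRS pH 5.4	original	KX905265
DL10a	Kluyveromyces marxianus	MRS pH 5.4	original	KX905266
DL10b	Kluyveromyces marxianus	MRS pH 5.4	original	KX905267
DL11	Kluyveromyces marxianus	MRS pH 5.4	original	KX905268
DL12	Kluyveromyces marxianus	MRS pH 5.4	original	KX905269
TJY52	Kluyveromyces marxianus	YPD+Cam	maintained	KX905270
TJY54	Kluyveromyces marxianus	YPD+Cam	maintained	KX905271
TJY59	Kluyveromyces marxianus	YPD+Cam	maintained	KX905272
TJY60	Kluyveromyces marxianus	YPD+Cam	maintained	KX905273
BL9	Saccharomyces cerevisiae	WL	original	KX905274
BL10	Saccharomyces cerevisiae	WL	original	KX905275
BL11	Saccharomyces cerevisiae	WL	original	KX905276
CL2	Saccharomyces cerevisiae	MRS	original	KX905277
CL3	Saccharomyces cerevisiae	MRS	original	KX905278
CL4	Saccharomyces cerevisiae	MRS	original	KX905279
DL3	Saccharomyces cerevisiae	MRS pH 5.4	original	KX905280
DL7	Saccharomyces cerevisiae	MRS pH 5.4	original	KX905281
TJY58	Saccharomyces cerevisiae	YPD+Cam	maintained	KX905282
TJY61	Saccharomyces cerevisiae	YPD+Cam	maintained	KX905283
BL2	Pichia fermentans	YPD	original	KX905284
CL1	Pichia fermentans	MRS	original	KX905285
CL7	Pichia fermentans	MRS	original	KX905286
DL1	Pichia fermentans	MRS pH 5.4	original	KX905287
DL8a	Pichia fermentans	MRS pH 5.4	original	KX905288
DL8b	Pichia fermentans	MRS pH 5.4	original	KX905289
DL9	Pichia fermentans	MRS pH 5.4	original	KX905290
TJY50	Pichia fermentans	YPD+Cam	maintained	KX905291
TJY53	Pichia fermentans	YPD+Cam	maintained	KX905292
TJY55	Pichia fermentans	YPD+Cam	maintained	KX905293
TJY56	Pichia fermentans	YPD+Cam	maintained	KX905294
TJY57	Pichia fermentans	YPD+Cam	maintained	KX905295
TJY51	Kazachstania unispora	YPD+Cam	maintained	KX905296
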