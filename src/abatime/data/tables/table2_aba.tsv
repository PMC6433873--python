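section	annotation	gene_id	fc_30	fc_60	fc_180
biosynthesis	ZEP	Phypa_186228	-	-	-
biosynthesis	SDR	Phypa_202254	-	-	-
biosynthesis	SDR	Phypa_125575	-	-	-
biosynthesis	AAO	Phypa_140802	-	-	-
biosynthesis	AAO	Phypa_106708	-	-	-
biosynthesis	AAO	Phypa_172226	-	-	-
biosynthesis	AAO	Phypa_162514	-	-	-
biosynthesis	MoCo	Phypa_118134	-	-	-
biosynthesis	NCED	Phypa_173118	9.09	8.03	6.34
biosynthesis	NCED	Phypa_159406	-	-	-
biosynthesis	NCED	Phypa_57876	-	2.26	4.73
biosynthesis	CYP707A	Phypa_130455	-	-	-
biosynthesis	CYP707A	Phypa_116547	-	-	-
biosynthesis	CYP707A	Phypa_69760	-	-	-
core_regulatory	PYL4-2	Phypa_209242	-	-	-
core_regulatory	PYL5	Phypa_213389	-	-	-
core_regulatory	ABI1	Phypa_32342	-	4.93	9.40
core_regulatory	ABI2	Phypa_13662	-	7.99	10.10
core_regulatory	OST1-1	Phypa_194508	9.01	14.17	21.69
core_regulatory	OST1-2	Phypa_215231	-	4.99	7.49
core_regulatory	OST1-4	Phypa_106968	15.23	19.63	20.48
core_regulatory	ABI3A	Phypa_158812	-	4.22	-
core_regulatory	ABI3B	Phypa_168363	-	5.15	-
core_regulatory	ABI4-like	Phypa_112999	-	-	-
signaling	HK1-like	Phypa_124824	-	3.92	-
signaling	PP2C; C subfamily	Phypa_165686	2.97	6.42	23
signaling	PP2C; C subfamily	Phypa_232556	-	7.51	21.2
signaling	GRF (14-3-3)	Phypa_217333	11.26	32.96	59.83
signaling	CBF/NF-Y	Phypa_8789	-	7.87	25.84
signaling	DREB; subfamily A-2	Phypa_18841	-	4.60	4.87
signaling	DREB; subfamily A-4	Phypa_28324	7.16	9.00	6.26
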