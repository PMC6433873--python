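gene_id	annotation	fc_30	fc_60	fc_180
Phypa_127570	Unknown	5.87	7.62	5.86
Phypa_138520	Unknown	7.46	5.79	7.51
Phypa_163620	Unknown	18.35	35.34	88.49
Phypa_167252	Unknown	4.74	4.40	4.78
Phypa_224374	Unknown	9.52	13.85	11.80
Phypa_75593	Unknown	30.25	33.24	27.93
Phypa_92162	Unknown	5.51	6.14	5.33
Phypa_167873	Chaperone protein DNAj chloroplast	7.21	9.09	7.43
Phypa_223189	Inositol-tetrakisphosphate 1-kinase 3	3.62	4.87	4.17
Phypa_38595	Two-component system sensor kinase	5.15	5.15	5.30
Phypa_38771	Chaperone protein	6.45	5.06	4.24
Phypa_39336	Copper chaperone	7.77	10.01	18.55
Phypa_51481	Multi-sensor hybrid histidine kinase	2.34	2.89	3.32
Phypa_90223	CBS domain protein	7.84	10.17	6.99
Phypa_117954	Glycerophosphoryl diester phosphodiesterase family protein	4.08	4.04	-
Phypa_188559	F-box protein family	5.99	5.51	-
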