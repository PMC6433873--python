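gene_id	annotation	fc_30	fc_60	fc_180
Phypa_120256	Galactan galactosyltransferase	-	2.56	6.41
Phypa_207105	Pectin lyase-like superfamily protein	-	3.65	6.45
Phypa_92683	Glycosyl transferase	-	2.37	3.11
Phypa_114674	Xyloglucan endotransglycosylase	-	-	6.82
Phypa_206446	Alpha-expansin	-	-	-5.06
Phypa_51702	Arabinogalactan protein	-	-	6.20
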