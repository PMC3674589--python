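Progression	GeneSymbol	corHuman	p.Human	corMouse	p.Mouse	MM.magenta
+	ADA	0.57	5.5e-7	0.62	9.2e-4	0.70
+	AIF1	0.51	1.6e-5	0.57	3.1e-3	0.67
+	C1QB	0.54	3.2e-6	0.65	4.6e-4	0.71
+	CASP3	0.59	1.8e-7	0.52	8.2e-3	0.59
+	CYBB	0.63	1.6e-8	0.56	3.4e-3	0.82
+	ENTPD1	0.51	1.2e-5	0.62	8.5e-4	0.66
+	GZMA	0.63	1.7e-8	0.70	1.0e-4	0.72
+	GZMK	0.61	5.8e-8	0.55	4.1e-3	0.63
+	HLA-DQB1	0.53	6.0e-6	0.65	5.0e-4	0.48
+	HLA-DRB1	0.53	5.9e-6	0.74	2.6e-5	0.89
+	IFIT1	0.59	2.6e-7	0.59	1.9e-3	0.43
+	ITGAX	0.51	1.2e-5	0.63	6.8e-4	0.68
+	LY86	0.58	4.4e-7	0.53	6.4e-3	0.78
+	PLEKHA2	0.63	1.5e-8	0.52	7.1e-3	0.87
+	STAT1	0.67	7.2e-10	0.64	5.2e-4	0.60
+	TLR7	0.63	1.6e-8	0.63	6.6e-4	0.61
-	ALDH3A2	-0.50	1.8e-5	-0.63	8.0e-4	-0.64
-	ANGPTL4	-0.50	1.9e-5	-0.58	2.6e-3	-0.40
-	ATP1B1	-0.56	1.0e-6	-0.58	2.5e-3	-0.62
-	CPT1A	-0.54	4.0e-6	-0.76	8.7e-6	-0.55
-	FAF1	-0.54	4.1e-6	-0.55	4.5e-3	-0.58
-	NEO1	-0.52	9.6e-6	-0.53	6.9e-3	-0.47
-	PALMD	-0.50	2.2e-5	-0.64	6.1e-4	-0.65
-	PDHA1	-0.58	3.9e-7	-0.63	8.0e-4	-0.71
-	PPFIBP2	-0.56	1.2e-6	-0.57	3.2e-3	-0.48
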