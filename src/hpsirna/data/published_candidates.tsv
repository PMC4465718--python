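sequence	strand	length	cpm_S-24-4D	cpm_S-24-13	cpm_S-24-15	cpm_WT
AAUGGUGCAGAUCUUUCUGGC	-	21	1262.59	89.94	50.69	1.35
GUAAUGGUGCAGAUCUUUCUG	-	21	88.62	6.49	4.75	0.15
AAUGGUAAUGGUGCAGAUCUU	-	21	34.45	2.67	1.36	0.04
AUGGUGCAGAUCUUUCUGGCU	-	21	19.19	0.96	0.84	0.02
CAGAUCUUUCUGGCUCACGGU	-	21	16.64	1.19	0.66	0.0
AGAUCUUUCUGGCUCACGGUA	-	21	16.36	0.84	0.64	0.0
GAUCUUUCUGGCUCACGGUAA	-	21	11.4	0.41	0.28	0.04
GCAGAUCUUUCUGGCUCACGG	-	21	5.14	0.23	0.17	0.0
AUCUUUCUGGCUCACGGUAAU	-	21	4.05	0.11	0.1	0.0
UGCAGAUCUUUCUGGCUCACG	-	21	3.27	0.18	0.0	0.0
UGGUGCAGAUCUUUCUGGCUC	-	21	3.06	0.28	0.16	0.0
UAAUGGUGCAGAUCUUUCUGG	-	21	2.79	0.14	0.13	0.0
AAAUGGUAAUGGUGCAGAUCU	-	21	2.25	0.24	0.11	0.0
GUGCAGAUCUUUCUGGCUCAC	-	21	1.58	0.08	0.1	0.0
GGUGCAGAUCUUUCUGGCUCA	-	21	1.0	0.04	0.04	0.0
AUGGUAAUGGUGCAGAUCUUU	-	21	0.97	0.04	0.0	0.0
UCUUUCUGGCUCACGGUAAUA	-	21	0.51	0.02	0.02	0.0
GAAAUGGUAAUGGUGCAGAUC	-	21	0.33	0.0	0.04	0.0
UGGUAAUGGUGCAGAUCUUUC	-	21	0.25	0.05	0.04	0.0
GGUAAUGGUGCAGAUCUUUCU	-	21	0.13	0.0	0.0	0.0
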