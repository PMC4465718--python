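>candidate_01 rna=AAUGGUGCAGAUCUUUCUGGC strand=-
AATGGTGCAGATCTTTCTGGC
>candidate_02 rna=GUAAUGGUGCAGAUCUUUCUG strand=-
GTAATGGTGCAGATCTTTCTG
>candidate_03 rna=AAUGGUAAUGGUGCAGAUCUU strand=-
AATGGTAATGGTGCAGATCTT
>candidate_04 rna=AUGGUGCAGAUCUUUCUGGCU strand=-
ATGGTGCAGATCTTTCTGGCT
>candidate_05 rna=CAGAUCUUUCUGGCUCACGGU strand=-
CAGATCTTTCTGGCTCACGGT
>candidate_06 rna=AGAUCUUUCUGGCUCACGGUA strand=-
AGATCTTTCTGGCTCACGGTA
>candidate_07 rna=GAUCUUUCUGGCUCACGGUAA strand=-
GATCTTTCTGGCTCACGGTAA
>candidate_08 rna=GCAGAUCUUUCUGGCUCACGG strand=-
GCAGATCTTTCTGGCTCACGG
>candidate_09 rna=AUCUUUCUGGCUCACGGUAAU strand=-
ATCTTTCTGGCTCACGGTAAT
>candidate_10 rna=UGCAGAUCUUUCUGGCUCACG strand=-
TGCAGATCTTTCTGGCTCACG
>candidate_11 rna=UGGUGCAGAUCUUUCUGGCUC strand=-
TGGTGCAGATCTTTCTGGCTC
>candidate_12 rna=UAAUGGUGCAGAUCUUUCUGG strand=-
TAATGGTGCAGATCTTTCTGG
>candidate_13 rna=AAAUGGUAAUGGUGCAGAUCU strand=-
AAATGGTAATGGTGCAGATCT
>candidate_14 rna=GUGCAGAUCUUUCUGGCUCAC strand=-
GTGCAGATCTTTCTGGCTCAC
>candidate_15 rna=GGUGCAGAUCUUUCUGGCUCA strand=-
GGTGCAGATCTTTCTGGCTCA
>candidate_16 rna=AUGGUAAUGGUGCAGAUCUUU strand=-
ATGGTAATGGTGCAGATCTTT
>candidate_17 rna=UCUUUCUGGCUCACGGUAAUA strand=-
TCTTTCTGGCTCACGGTAATA
>candidate_18 rna=GAAAUGGUAAUGGUGCAGAUC strand=-
GAAATGGTAATGGTGCAGATC
>candidate_19 rna=UGGUAAUGGUGCAGAUCUUUC strand=-
TGGTAATGGTGCAGATCTTTC
>candidate_20 rna=GGUAAUGGUGCAGAUCUUUCU strand=-
GGTAATGGTGCAGATCTTTCT
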