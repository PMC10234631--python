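# data/

External inputs that cannot be generated.

`ms_snp_gene_pairs_supp3.tsv` — the published SNP–gene susceptibility pair
table of the original study (columns: `snp_id`, `gene_id`, `odds_ratio`,
`nes`; tab-separated, `NA` for missing NES). Place it here to run the
reclassification check in `tests/test_acceptance.py`; it is distributed
with the original study, not with this package. Other column layouts can be
adapted with the column-mapping argument of
`foxsplice.ms_catalog.build_pairs`.
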