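# foxsplice

Analysis pipeline for studying how depletion of an RNA helicase reshapes a
T-cell transcriptome, and for characterizing the sequence feature — a
cytosine-rich polypyrimidine (py) tract — that marks the retained introns
which respond to it.

The package re-implements, as tested, reusable code over synthetic stand-ins
for the original sequencing summaries, four computational arms:

1. **DEG filtering** (`foxsplice.deg`) — gene-level knockdown RNA-seq tables
   are filtered by mean expression (RPKM ≥ 2), called by a per-hairpin
   fold-change magnitude cutoff (|score| > 0.3 for the strong shRNA, > 0.1
   for the weak one; strict inequalities), and intersected across donors.
2. **Risk-gene classification** (`foxsplice.ms_catalog`) — SNP–gene
   susceptibility pairs carrying a risk-allele odds ratio (OR) and a signed
   eQTL normalized effect size (NES) are harmonized to OR > 1 and labeled
   *pathogenic* when the risk allele associates with higher expression
   (NES < 0) and *protective* when with lower expression (NES > 0).
3. **Overlap enrichment** (`foxsplice.enrichment`) — the overlap *k* between
   *n₁* DEGs and *n₂* target genes in a universe of *N* expressed genes is
   tested by resampling *n₁* genes without replacement *R* times (default
   100,000); the empirical p is the fraction of resamples with overlap ≥ *k*.
   Because sampling is without replacement the null is exactly
   hypergeometric, P(X ≥ k) = Σ_{j≥k} C(n₂,j)·C(N−n₂,n₁−j)/C(N,n₁), which
   serves as a built-in oracle for every Monte Carlo result.
4. **Splice-site and retention analysis** (`foxsplice.splice`,
   `foxsplice.retention`) — 9-nt donor (exon −3..−1 + intron +1..+6) and
   23-nt acceptor (intron −20..−1 + exon +1..+3) windows are extracted
   strand-aware from FASTA + BED; the py tract is positions −20..−3 (the G
   of the 3′SS AG is −1). Events with MV|dPSI| ≥ 0.15 and dPSI > 0 are the
   retained set, compared against a seeded 500-event sample of unchanged
   introns on position-weight-matrix site scores (log₂ odds in bits, with
   median/MAD outlier trimming) and per-base py-tract frequencies, by
   two-sided rank-sum tests.

A synthetic-data module (`foxsplice.synthetic`) generates every input with
the statistical structure the analysis assumes — spiked DEG fractions,
OR/NES sign structure with missingness, py tracts drawn from per-position
base profiles, and a logistic link between py-tract C content and intron
retention — with truth labels returned for recovery testing.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(each is a thin driver over the package; outputs land in `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_deg_filter.py
python analysis/03_classify_ms_genes.py
python analysis/04_enrichment.py --seed 1 --resamples 20000
python analysis/05_splice_sites.py
python analysis/06_retention_compare.py --seed 1
```

Selected output at seed 1:

```
518 DEGs called in both donors (272 up, 246 down, 0 discordant)
recovery vs spiked truth: sensitivity 1.0000, false-positive rate 0.0000

500 SNP-gene pairs: 241 pathogenic, 238 protective, 21 excluded (missing NES)

universe: 6389 expressed genes; 272 up / 246 down DEGs
  up_pathogenic    k= 11 (n1=272, n2=150)  empirical p  0.0557  exact p 0.0544  null mode 6
planted excess   k= 30  empirical p < 5e-05  exact p 2.87e-08

compared 437 retained vs 463 control introns (1 score outliers removed)
  C frequency retained/control: 0.546 / 0.468  p = 1.48e-22
  U frequency retained/control: 0.182 / 0.211  p = 2.82e-06
```

Reading this: the spiked DEGs are recovered exactly by the filter chain; the
pair classifier splits the susceptibility genes by eQTL direction (the
synthetic table plants ~50/50); the enrichment contrasts sit at their null
when no overlap is planted, the empirical and exact p agree to Monte Carlo
precision, and a planted 30-gene excess is detected decisively; and the
retained introns show the planted composition signature — more C, less U in
the py tract — at high significance.

The same pipeline is scriptable end to end via the `foxsplice` CLI
(`simulate`, `deg`, `classify`, `enrich`, `splice-sites`, `retention`,
`run`, `validate`), configured by YAML and a single seed.

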