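# Methods

## Scope and shape

The package is organized as an analysis project: the numbered scripts under
`analysis/` narrate the study over synthetic data, while every computation
lives in `src/foxsplice/` where the tests and `scripts/acceptance.py` import
it. The stages mirror a knockdown RNA-seq study of an RNA helicase in
primary CD4⁺ T cells: differential expression, direction-of-effect
classification of disease-susceptibility genes, overlap enrichment between
the two, and sequence characterization of the retained introns that respond
to the knockdown. Read alignment, fold-change estimation and PSI
quantification are out of scope — the pipeline consumes the summary tables
those tools emit.

## Synthetic data: what it emulates, and what it does not

All inputs are generated by `foxsplice.synthetic` under a single
`SimulationConfig`. Defaults are the study conditions the tests assume;
they were chosen once, from the scale of the emulated study, and are not
tuning knobs.

**Expression table.** Per-gene baseline RPKM is log-normal
(`rpkm_log_mean=1.0`, `rpkm_log_sd=1.0`, natural-log scale — a broad
distribution with median e ≈ 2.7, typical of bulk RNA-seq after light
filtering). Two donors, three libraries each (control NTC plus two
knockdown hairpins Sh3/Sh5), with multiplicative per-library log-normal
noise (σ = 0.1). A `deg_fraction = 0.05` subset of genes (≈ 500 of 10,000,
the order of the emulated study's 762) is spiked: their fold-change score
is ±(`deg_effect` + |N(0, 0.1)|) with a common sign across all comparisons,
and their knockdown libraries are shifted by 2^(±effect); non-DEG scores
are N(0, 0.05). Spiked genes are placed on baselines above the expression
filter (base RPKM ≥ 4), so recovery sensitivity measures the filter chain
rather than spike placement. Not emulated: count noise, length/GC bias,
donor-specific expression structure, or correlated genes — so perfect
recovery here shows the cutoffs are implemented exactly, not that real data
would separate this cleanly.

**SNP–gene pair table.** `n_ms_genes = 500` pairs (the emulated catalog has
558 genes / 539 classifiable pairs), genes drawn from the expression
universe so overlap tests are well defined. OR = exp(0.05 + |N(0, 0.25)|)
> 1 by construction; NES magnitude 0.05 + |N(0, 0.4)| with sign negative
for an expected `frac_pathogenic = 0.5` of non-missing rows;
`frac_missing_nes = 0.05` rows lack NES (the real catalog lost ≈ 3.5% of
pairs to missing expression profiles). One SNP per gene by default, so
gene-level conflicts arise only in constructed test inputs.

**Introns.** Each intron is `gt` + 4 random nt + random filler + an 18-nt
py tract + `ag`, length 70–120 nt, with 8-nt uniform exonic flanks, laid
alternately on the forward and reverse strands of one synthetic chromosome
with 30-nt random spacers. Py-tract bases are drawn independently per
position: the C-rich profile is P(A, C, G, U) = (0.15, 0.5, 0.15, 0.2) at
every position, the U-rich profile its mirror. Real py tracts have
dinucleotide structure and position-dependent composition; the analysis is
position-wise, so independence is the matching null. Note an exact
consequence of these marginals: the probability that a single 18-nt C-rich
tract has strictly more C than U is 0.9271 (trinomial enumeration), so
per-intron classification is ≈ 93% C-rich while the per-gene average over
3 introns is C-rich with near certainty.

**Retention events.** One retained-intron event per intron, with retention
indicator Bernoulli(logit⁻¹(`retention_intercept` + `retention_slope` · C)),
where C is the py-tract cytosine fraction. Defaults slope 6.0, intercept
−3.0 put retention at 50% for C = 0.5 and yield ≈ 440 retained / 460
unchanged events at `n_introns = 900` — the scale of the emulated
comparison (≈ 400 retained vs 500 sampled controls). Retained events get
dPSI > 0 and MV|dPSI| ≥ 0.15; unchanged events fall below the cutoff, so
the event filter reproduces the truth labels by construction and the
interesting recovery question is the composition contrast downstream.

## Statistical procedures

**DEG chain.** Mean-RPKM filter is ≥ 2 (the discard rule is "averaging
less than 2", so the boundary is kept); fold-change cutoffs are strict
(0.31 passes 0.3, 0.30 does not). The libraries entering the expression
average are configurable: all libraries of the comparison (default) or
control-only — both appear in the emulated study for different purposes,
and neither is asserted as the original DEG-stage choice. Donor direction
is reported, not enforced: discordant genes stay in the intersection but
are excluded from the directional splits.

**Classification.** Rows with OR < 1 are harmonized by (OR, NES) →
(1/OR, −NES): the risk allele is defined by OR > 1 and allele flipping
negates the eQTL sign, making the rule an involution (property-tested).
OR = 1 or NES = 0 after harmonization is `unclassified`; missing NES is
`excluded_missing`; genes with both labels across their SNPs are
quarantined as `conflicted` rather than tie-broken, since no tie rule is
stated in the emulated analysis and the quarantine keeps the discrepancy
auditable. The NES sign convention is isolated behind one flag.

**Enrichment.** Resampling is genuinely without replacement: each of the R
draws ranks i.i.d. uniform keys and takes the n₁ smallest, counting marked
genes among them (vectorized, bounded scratch memory). The empirical p is
the raw fraction of draws with overlap ≥ k — not the (r+1)/(R+1)
estimator — with a "< 1/R" floor flag when zero, matching the emulated
procedure's reporting. The hypergeometric tail (scipy, log-space) is the
exact oracle; tests require agreement within 3 Monte Carlo standard errors
across a grid of enumerable instances, and the resampled null mode to equal
the pmf argmax (instances with tied maxima are excluded — the symmetric
case N = 2·n₂ can tie exactly). All four directional contrasts share one
seed so symmetric inputs give identical results. The universe defaults to
all genes passing the expression filter; it is configurable because the
expressed-gene universe of the emulated study is not published.

**Splice sites.** Coordinates are BED-style 0-based half-open on the
forward strand; windows are reported in transcript orientation with
lowercase intron / uppercase exon, positions labeled with the 3′SS AG
guanine at −1. Non-canonical boundaries are flagged, never dropped.
Position frequency matrices exclude ambiguous bases from column
denominators and reject sequences with > 10% N. Information content is
2 + Σ p·log₂p bits without small-sample correction, keeping the exact
[0, 2] bounds; logo letter height is p·IC, and logos are exported as
matrices (no image rendering). Py-tract classification is mean C > mean U
over positions −20..−3 (tie → neither) — a deliberate operationalization;
no threshold is inventable from the emulated description, and the rule is
a config point.

**Site scoring.** A position weight matrix (per-position
log₂((p + pseudocount-adjusted)/background), summed over the window) stands
behind the scoring interface; externally computed score columns (e.g.
maximum-entropy scores) can be passed to the comparison unchanged and
bypass the internal scorer. Two consequences to keep in mind: the score is
a monotone typicality measure *relative to its training set*, and when
trained on the study's own intron population (as the analysis drivers do)
a majority-C-rich population scores C-rich acceptors *higher* — the
opposite sign from an external spliceosomal-strength model, under which
C-rich tracts are weak. Conclusions about strength direction therefore
require an externally trained or supplied score; the package's own
comparisons treat the score as a covariate, with the composition contrast
carrying the biology.

**Retention comparison.** The MV|dPSI| cutoff is inclusive (≥ 0.15); the
control is a seeded uniform sample without replacement of 500 unchanged
events (all of them, with a warning, if fewer). Outlier trimming on score
distributions is median ± k·MAD with MAD scaled to estimate σ and
k = Φ⁻¹(1 − q/2) ≈ 2.81 at the nominal q = 0.5% — a location-scale
stand-in for regression-based outlier removal, which reduces to exactly
this for a single-sample score distribution; it is switchable off. Rank
tests are two-sided (sidedness is not stated in the emulated analysis);
scipy's exact small-sample / tie-corrected asymptotic policy applies.
Events without an extractable intron sequence are excluded from
composition comparisons and counted.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; the pipeline expands one
master seed into independent per-stage seeds by hashing the stage name, and
repeated runs with the same configuration are byte-identical, report
included. The test suite runs the power analyses at the generator's study
conditions (900 events, 100 seeds for the planted-association power check;
300 events, 500 seeds for the type-I calibration; R = 50,000 for the
oracle grid) — sizes chosen so the checks are statistically meaningful at
desk scale. `scripts/acceptance.py` re-runs the full set in a few seconds.

## Known limitations

- The synthetic world has no splice-graph structure, no read-level noise,
  and no correlation between expression, splicing and genotype beyond the
  single planted logistic link; passing recovery tests demonstrates the
  procedures, not their power on real data.
- The published headline numbers of the emulated study (762 DEGs, the
  41-gene overlap with empirical p = 0.00013 and null mode 23, 784 retained
  events) depend on deposited sequencing data and an unpublished universe
  size and are not reproducible from summary tables; the package reproduces
  the *procedures* and verifies them against exact oracles and planted
  truth instead.
- The pathogenic/protective reclassification of the original SNP–gene pair
  table (250/262 genes) runs only when that published table is supplied at
  `data/ms_snp_gene_pairs_supp3.tsv`.
- Gene-level conflict handling (the `conflicted` set) and the C-rich rule
  are package decisions at points the emulated analysis leaves unstated;
  both are isolated and configurable.
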