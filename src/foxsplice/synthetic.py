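"""Seeded generators for every pipeline input.

The generators emulate the summary tables the analysis consumes rather than
reads: a gene-level expression table with per-library RPKM and per-comparison
fold-change scores and a spiked DEG fraction; a SNP-gene susceptibility pair
table with odds ratios, signed eQTL effect sizes and missingness; intron sets
whose py-tract base composition follows configurable per-position profiles
(laid out on a synthetic genome so FASTA/BED extraction can be exercised on
both strands); and a differential-splicing event table in which retention
probability increases with py-tract C content through a logistic link.

Truth labels are returned alongside every stochastic table; downstream stages
never see them outside of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from foxsplice.config import ALPHABET, InvalidConfigError, SimulationConfig
from foxsplice.splice import IntronRecord, make_windows

CONDITIONS = ("NTC", "Sh3", "Sh5")
SHRNAS = ("Sh3", "Sh5")

_STREAM = {"expression": 1, "pairs": 2, "introns_crich": 3, "introns_urich": 4,
           "events": 5, "genome": 6}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stream]])


def donor_labels(config: SimulationConfig) -> list[str]:
    return [f"Donor{i + 1}" for i in range(config.n_donors)]


def rpkm_col(donor: str, condition: str) -> str:
    return f"rpkm_{donor}_{condition}"


def gfold_col(donor: str, shrna: str) -> str:
    return f"gfold_{donor}_{shrna}"


# ---------------------------------------------------------------------------
# expression


def gen_expression_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene-level expression/fold-change table plus truth labels.

    Per-library RPKM is log-normal around a gene baseline; a ``deg_fraction``
    subset of genes carries concordant fold-change scores of magnitude
    ``deg_effect + |N(0, 0.1)|`` in every donor/shRNA comparison (knockdown
    libraries shifted accordingly), the remainder scores ``N(0, sd)`` near
    zero. Spiked genes are given baselines above the expression filter so DEG
    recovery measures the filter chain, not spike placement.
    """
    if config.n_genes < 1:
        raise InvalidConfigError("n_genes must be positive")
    rng = _rng(config, "expression")
    n = config.n_genes
    donors = donor_labels(config)

    base = rng.lognormal(config.rpkm_log_mean, config.rpkm_log_sd, size=n)
    is_deg = rng.random(n) < config.deg_fraction
    direction = np.where(rng.random(n) < 0.5, 1, -1)
    direction[~is_deg] = 0
    # expressed baseline for spiked genes: 4 + lognormal keeps them above the filter
    base[is_deg] = 4.0 + rng.lognormal(config.rpkm_log_mean, config.rpkm_log_sd,
                                       size=int(is_deg.sum()))

    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    data = {"gene_id": gene_ids}
    for donor in donors:
        for cond in CONDITIONS:
            noise = rng.lognormal(0.0, 0.1, size=n)
            shift = np.ones(n)
            if cond != "NTC":
                shift = np.where(is_deg, 2.0 ** (direction * config.deg_effect), 1.0)
            data[rpkm_col(donor, cond)] = base * noise * shift
    for donor in donors:
        for sh in SHRNAS:
            score = rng.normal(0.0, config.nondeg_score_sd, size=n)
            spiked = direction * (config.deg_effect + np.abs(rng.normal(0.0, 0.1, size=n)))
            data[gfold_col(donor, sh)] = np.where(is_deg, spiked, score)

    table = pd.DataFrame(data)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_deg": is_deg,
        "direction": np.select([direction > 0, direction < 0], ["up", "down"], default="none"),
    })
    return table, truth


# ---------------------------------------------------------------------------
# SNP-gene susceptibility pairs


def gen_ms_pair_table(config: SimulationConfig) -> pd.DataFrame:
    """Generate a SNP-gene susceptibility pair table.

    All odds ratios exceed 1 by construction (the risk allele defines the
    table's orientation); among non-missing rows an expected
    ``frac_pathogenic`` have NES < 0, and ``frac_missing_nes`` rows lack an
    eQTL effect size entirely (NES written as NA). Susceptibility genes are
    drawn from the same gene universe as the expression table so overlap
    tests against DEG sets are well defined.
    """
    rng = _rng(config, "pairs")
    n = config.n_ms_genes
    if n > config.n_genes:
        raise InvalidConfigError("n_ms_genes cannot exceed n_genes")
    gene_ids = [f"G{i:05d}" for i in sorted(rng.choice(config.n_genes, size=n, replace=False))]
    snp_ids = [f"rs{100000 + i}" for i in rng.choice(10 * n, size=n, replace=False)]
    odds_ratio = np.exp(0.05 + np.abs(rng.normal(0.0, 0.25, size=n)))
    missing = rng.random(n) < config.frac_missing_nes
    pathogenic = rng.random(n) < config.frac_pathogenic
    magnitude = 0.05 + np.abs(rng.normal(0.0, 0.4, size=n))
    nes = np.where(pathogenic, -magnitude, magnitude)
    nes[missing] = np.nan
    return pd.DataFrame({
        "snp_id": snp_ids,
        "gene_id": gene_ids,
        "odds_ratio": odds_ratio,
        "nes": nes,
    })


# ---------------------------------------------------------------------------
# introns and a synthetic genome


@dataclass
class SyntheticIntronSet:
    """Intron records with their backing genome and raw transcript sequences."""

    records: list[IntronRecord]
    genome: dict[str, str]
    #: transcript-oriented (exon_left, intron, exon_right) per record
    parts: list[tuple[str, str, str]]

    def bed_rows(self) -> list[tuple]:
        return [(r.chrom, r.start, r.end, r.name, 0, r.strand) for r in self.records]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(ALPHABET)[rng.integers(0, 4, size=length)])


def gen_intron_set(config: SimulationConfig, profile: str = "crich", n: int | None = None,
                   introns_per_gene: int = 3, flank: int = 8,
                   spacer: int = 30, chrom: str = "chrS",
                   min_len: int = 70, max_len: int = 120) -> SyntheticIntronSet:
    """Generate ``n`` introns with py tracts drawn from the named profile.

    Every intron starts ``gt`` and ends with an 18-nt py tract followed by
    ``ag``; py-tract bases are drawn independently per position from the
    configured profile; donor tail and mid-intron filler and the exonic flanks
    are uniform. The introns are laid onto a synthetic chromosome with
    alternating strands (even indices forward, odd reverse) so that interval
    extraction from FASTA/BED can be round-tripped.
    """
    prof = config.profile(profile)
    rng = _rng(config, f"introns_{profile}")
    if n is None:
        n = config.n_introns
    letters = np.array(ALPHABET)

    ilens = rng.integers(min_len, max_len + 1, size=n)
    # inverse-CDF draw of all py tracts at once: index = #{cumulative bins <= u}
    cum = prof.cumsum(axis=1)
    u = rng.random((n, prof.shape[0]))
    tract_idx = (u[:, :, None] >= cum[None, :, :]).sum(axis=2)

    records: list[IntronRecord] = []
    parts: list[tuple[str, str, str]] = []
    pieces: list[str] = []
    offset = 0
    for i in range(n):
        ilen = int(ilens[i])
        tract = "".join(letters[tract_idx[i]])
        intron = "GT" + _random_seq(rng, 4) + _random_seq(rng, ilen - 26) + tract + "AG"
        exon_l = _random_seq(rng, flank)
        exon_r = _random_seq(rng, flank)
        five_ss, three_ss, py_tract, canonical = make_windows(exon_l, intron, exon_r)

        strand = "+" if i % 2 == 0 else "-"
        locus = exon_l + intron + exon_r
        if strand == "-":
            locus = reverse_complement(locus)
        gap = _random_seq(rng, spacer)
        pieces.append(gap)
        offset += spacer
        locus_start = offset
        pieces.append(locus)
        offset += len(locus)
        # symmetric flanks: the intron occupies the same genomic span on either strand
        start = locus_start + flank
        end = start + ilen

        gene_id = f"SYN{i // introns_per_gene:04d}"
        records.append(IntronRecord(gene_id, i % introns_per_gene, chrom, start, end,
                                    strand, five_ss, three_ss, py_tract, canonical))
        parts.append((exon_l, intron, exon_r))
    pieces.append(_random_seq(rng, spacer))
    return SyntheticIntronSet(records, {chrom: "".join(pieces)}, parts)


# ---------------------------------------------------------------------------
# retention events


def pytract_c_fraction(record: IntronRecord) -> float:
    tract = record.py_tract.upper()
    return tract.count("C") / len(tract)


def gen_retention_events(introns: SyntheticIntronSet | list[IntronRecord],
                         config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a differential-splicing event table over an intron set.

    Each intron yields one retained-intron event whose retention indicator is
    Bernoulli with ``logit p = retention_intercept + retention_slope * C``,
    where C is the intron's py-tract cytosine fraction. Retained events carry
    dPSI > 0 with MV|dPSI| >= 0.15; unaffected events fall below the cutoff.
    """
    records = introns.records if isinstance(introns, SyntheticIntronSet) else list(introns)
    if not records:
        raise ValueError("intron set is empty")
    rng = _rng(config, "events")
    n = len(records)
    cfrac = np.array([pytract_c_fraction(r) for r in records])
    logit = config.retention_intercept + config.retention_slope * cfrac
    p_retain = 1.0 / (1.0 + np.exp(-logit))
    retained = rng.random(n) < p_retain

    mv = np.where(retained,
                  np.minimum(0.15 + rng.exponential(0.08, size=n), 0.95),
                  rng.uniform(0.0, 0.149, size=n))
    dpsi = np.where(retained,
                    np.minimum(mv * 100.0 * rng.uniform(1.0, 1.5, size=n), 100.0),
                    np.clip(rng.normal(0.0, 2.0, size=n), -14.9, 14.9))

    events = pd.DataFrame({
        "event_id": [f"IR{i:05d}" for i in range(n)],
        "gene_id": [r.gene_id for r in records],
        "event_type": "retained_intron",
        "chrom": [r.chrom for r in records],
        "start": [r.start for r in records],
        "end": [r.end for r in records],
        "strand": [r.strand for r in records],
        "dpsi": dpsi,
        "mv_dpsi": mv,
    })
    truth = pd.DataFrame({"event_id": events["event_id"], "retained": retained})
    return events, truth


# ---------------------------------------------------------------------------
# writers (all plain text: TSV, FASTA, BED)

_FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(rows: list[tuple], path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows
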