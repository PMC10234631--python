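"""Classification of disease-susceptibility genes by eQTL direction of effect.

Each SNP-gene pair carries the odds ratio of the disease risk allele and the
signed eQTL normalized effect size (NES) of that allele on the gene in
lymphoblastoid cells. With the table harmonized so OR > 1 (the risk allele),
NES < 0 corresponds to higher expression of the gene on the risk allele and
the gene is called *pathogenic*; NES > 0 corresponds to lower expression and
the gene is called *protective*. Rows with OR < 1 are flipped to the risk
allele by (OR, NES) -> (1/OR, -NES). Pairs lacking NES are excluded from
classification; genes whose pairs disagree are quarantined as *conflicted*
rather than silently assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

LABELS = ("pathogenic", "protective", "unclassified", "excluded_missing")

#: default column mapping for pair tables (a supplementary-table layout can be
#: adapted by overriding these names)
DEFAULT_COLUMNS = {"snp": "snp_id", "gene": "gene_id", "or": "odds_ratio", "nes": "nes"}


@dataclass(frozen=True)
class MsGenePair:
    snp_id: str
    gene_id: str
    odds_ratio: float
    nes: float | None
    label: str


@dataclass
class MsGeneSets:
    """Gene-level collapse of pair labels."""

    susceptibility: set[str]
    pathogenic: set[str]
    protective: set[str]
    conflicted: set[str]


def classify_pair(odds_ratio: float, nes: float,
                  harmonize: bool = True, flip_nes_sign: bool = False) -> str:
    """Label one SNP-gene pair from its odds ratio and eQTL effect size.

    ``flip_nes_sign`` inverts the NES sign convention (isolated here because
    the printed convention — NES < 0 meaning higher expression on the risk
    allele — reads counterintuitively).
    """
    if not odds_ratio > 0 or math.isnan(odds_ratio):
        raise ValueError(f"odds ratio must be positive, got {odds_ratio!r}")
    if harmonize and odds_ratio < 1:
        odds_ratio, nes = 1.0 / odds_ratio, -nes
    if flip_nes_sign:
        nes = -nes
    if odds_ratio == 1 or nes == 0:
        return "unclassified"
    if nes < 0:
        return "pathogenic"
    return "protective"


def build_pairs(pair_table: pd.DataFrame,
                columns: Mapping[str, str] = DEFAULT_COLUMNS,
                harmonize: bool = True, flip_nes_sign: bool = False) -> list[MsGenePair]:
    """Build classified SNP-gene pairs from a table with OR and NES columns.

    Rows with missing NES are labeled ``excluded_missing`` (they stay in the
    susceptibility gene universe but never enter classification counts).
    Duplicate (snp, gene) rows are an error unless their values agree.
    """
    cols = {**DEFAULT_COLUMNS, **dict(columns)}
    snp_c, gene_c, or_c, nes_c = cols["snp"], cols["gene"], cols["or"], cols["nes"]
    for c in (snp_c, gene_c, or_c):
        if c not in pair_table.columns:
            raise KeyError(f"pair table lacks required column {c!r}")
    has_nes = nes_c in pair_table.columns

    keyed = pair_table.drop_duplicates()
    dup = keyed.duplicated(subset=[snp_c, gene_c])
    if dup.any():
        offender = keyed.loc[dup, [snp_c, gene_c]].iloc[0].tolist()
        raise ValueError(f"duplicate (snp, gene) rows with conflicting values: {offender}")

    pairs = []
    for row in keyed.itertuples(index=False):
        row = row._asdict()
        odds_ratio = float(row[or_c])
        nes = row[nes_c] if has_nes else None
        if nes is None or (isinstance(nes, float) and math.isnan(nes)):
            pairs.append(MsGenePair(str(row[snp_c]), str(row[gene_c]),
                                    odds_ratio, None, "excluded_missing"))
            continue
        label = classify_pair(odds_ratio, float(nes), harmonize, flip_nes_sign)
        pairs.append(MsGenePair(str(row[snp_c]), str(row[gene_c]),
                                odds_ratio, float(nes), label))
    return pairs


def collapse_to_genes(pairs: Iterable[MsGenePair]) -> MsGeneSets:
    """Collapse pair labels to gene sets.

    A gene is pathogenic (protective) iff at least one of its pairs carries
    that label and none carries the opposite; genes with pairs of both labels
    are reported as conflicted.
    """
    pairs = list(pairs)
    susceptibility = {p.gene_id for p in pairs}
    has_path = {p.gene_id for p in pairs if p.label == "pathogenic"}
    has_prot = {p.gene_id for p in pairs if p.label == "protective"}
    conflicted = has_path & has_prot
    return MsGeneSets(
        susceptibility=susceptibility,
        pathogenic=has_path - conflicted,
        protective=has_prot - conflicted,
        conflicted=conflicted,
    )


def label_counts(pairs: Iterable[MsGenePair]) -> dict[str, int]:
    counts = dict.fromkeys(LABELS, 0)
    for p in pairs:
        counts[p.label] += 1
    return counts
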