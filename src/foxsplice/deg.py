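"""Differential-expression calling from gene-level summary tables.

The chain mirrors the knockdown RNA-seq analysis it emulates: discard genes
averaging an RPKM below 2, call genes whose fold-change score clears a
per-shRNA magnitude cutoff (|score| > 0.3 for the strong hairpin Sh3,
> 0.1 for the weaker Sh5; strict inequalities), and keep only genes passing
in every donor. Direction across donors is reported, not enforced: genes with
discordant signs stay in the intersection but are excluded from the
directional splits used by the enrichment contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from foxsplice.synthetic import gfold_col, rpkm_col

DEFAULT_CUTOFFS = {"Sh3": 0.3, "Sh5": 0.1}
MIN_RPKM = 2.0


class ConfigurationError(KeyError):
    """A named library, comparison, or shRNA is absent from the table."""


@dataclass(frozen=True)
class DegCall:
    """One gene's DEG call with the comparisons it passed and its direction."""

    gene_id: str
    comparisons_passed: frozenset[str]
    direction: str  # "up" | "down" | "discordant"


def _require_columns(table: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ConfigurationError(f"table lacks columns: {missing}")


def filter_expressed(table: pd.DataFrame, libraries: Iterable[str],
                     min_rpkm: float = MIN_RPKM) -> set[str]:
    """Genes whose mean RPKM over the named libraries is >= ``min_rpkm``.

    The discard rule is "averaging less than ``min_rpkm``", so a mean of
    exactly ``min_rpkm`` is kept.
    """
    cols = list(libraries)
    if not cols:
        raise ConfigurationError("at least one library label is required")
    _require_columns(table, cols)
    means = table[cols].mean(axis=1)
    return set(table.loc[means >= min_rpkm, "gene_id"])


def comparison_libraries(donor: str, shrna: str, mode: str = "all") -> list[str]:
    """RPKM library columns entering the expression average for one comparison.

    ``mode='all'`` averages control and knockdown libraries of the comparison
    (the default rule); ``mode='ntc_only'`` averages the control libraries
    alone (the variant used for gene-set enrichment input elsewhere).
    """
    if mode == "all":
        return [rpkm_col(donor, "NTC"), rpkm_col(donor, shrna)]
    if mode == "ntc_only":
        return [rpkm_col(donor, "NTC")]
    raise ConfigurationError(f"unknown expression-filter mode {mode!r}")


def call_degs(table: pd.DataFrame, shrna: str, donor: str,
              expressed: set[str] | None = None,
              cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS) -> set[str]:
    """Genes with |fold-change score| strictly above the per-shRNA cutoff."""
    if shrna not in cutoffs:
        raise ConfigurationError(f"unknown shRNA label {shrna!r}; known: {sorted(cutoffs)}")
    col = gfold_col(donor, shrna)
    _require_columns(table, [col])
    called = set(table.loc[table[col].abs() > cutoffs[shrna], "gene_id"])
    if expressed is not None:
        called &= expressed
    return called


def intersect_donors(per_donor_calls: Mapping[str, set[str]], table: pd.DataFrame,
                     shrna: str = "Sh3") -> list[DegCall]:
    """Genes called in every donor, annotated with cross-donor direction.

    Direction is ``up`` iff every passing comparison's score is positive,
    ``down`` iff every one is negative, else ``discordant``.
    """
    if len(per_donor_calls) < 2:
        raise ValueError("donor intersection requires at least two donors")
    donors = sorted(per_donor_calls)
    common = set.intersection(*(set(per_donor_calls[d]) for d in donors))
    cols = {d: gfold_col(d, shrna) for d in donors}
    _require_columns(table, cols.values())
    scores = table.set_index("gene_id")[[cols[d] for d in donors]]

    calls = []
    for gene in sorted(common):
        vals = scores.loc[gene]
        if (vals > 0).all():
            direction = "up"
        elif (vals < 0).all():
            direction = "down"
        else:
            direction = "discordant"
        passed = frozenset(f"{d}_{shrna}" for d in donors)
        calls.append(DegCall(gene, passed, direction))
    return calls


def split_by_direction(calls: Iterable[DegCall]) -> tuple[set[str], set[str]]:
    """Partition non-discordant calls into (up, down); discordant genes drop out."""
    up = {c.gene_id for c in calls if c.direction == "up"}
    down = {c.gene_id for c in calls if c.direction == "down"}
    return up, down


def deg_pipeline(table: pd.DataFrame, donors: Iterable[str], shrna: str = "Sh3",
                 min_rpkm: float = MIN_RPKM, expression_mode: str = "all",
                 cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS) -> list[DegCall]:
    """Compose filter -> call -> intersect for one shRNA across donors."""
    per_donor = {}
    for donor in donors:
        expressed = filter_expressed(
            table, comparison_libraries(donor, shrna, expression_mode), min_rpkm)
        per_donor[donor] = call_degs(table, shrna, donor, expressed, cutoffs)
    return intersect_donors(per_donor, table, shrna)
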