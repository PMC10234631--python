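"""Selection of knockdown-sensitive introns and sequence-feature comparisons.

Splicing events whose minimum |dPSI| at 95% confidence (MV|dPSI|) reaches the
significance cutoff (0.15, inclusive) are split by dPSI sign into more- and
less-retained sets; the more-retained set is compared against a seeded random
sample of unchanged introns (the paper-scale control is 500 events) on
splice-site strength scores and on py-tract base composition, using two-sided
rank-sum tests. A median/MAD trimming rule calibrated to a nominal
false-removal rate stands in for regression-based outlier removal on the
score distributions (single-sample location-scale trimming; switchable off).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from foxsplice.splice import IntronRecord, pytract_mean_frequencies

MV_DPSI_CUTOFF = 0.15
BASES = ("A", "C", "G", "U")


@dataclass
class ComparisonReport:
    """Two-group comparison of splice-site scores and py-tract composition."""

    n_retained: int
    n_control: int
    score_medians: dict = field(default_factory=dict)   # {"5ss": (medA, medB), ...}
    score_pvalues: dict = field(default_factory=dict)   # {"5ss": p, ...}
    composition_means: dict = field(default_factory=dict)  # {"C": (meanA, meanB), ...}
    composition_pvalues: dict = field(default_factory=dict)
    outliers_removed: int = 0
    n_missing_sequence: int = 0
    tests_suppressed: bool = False


def select_events(events: pd.DataFrame,
                  cutoff: float = MV_DPSI_CUTOFF) -> pd.DataFrame:
    """Classify each event as more_retained / less_retained / unchanged.

    An event is significantly changed when MV|dPSI| >= cutoff (inclusive);
    its sign of dPSI decides the retention direction. Returns a copy with a
    ``class`` column.
    """
    out = events.copy()
    significant = out["mv_dpsi"] >= cutoff
    out["class"] = np.select(
        [significant & (out["dpsi"] > 0), significant & (out["dpsi"] < 0)],
        ["more_retained", "less_retained"],
        default="unchanged",
    )
    return out


def sample_unaffected(unchanged_ids, n: int = 500, seed: int = 0) -> list[str]:
    """Seeded uniform sample without replacement from the unchanged events."""
    ids = sorted(str(x) for x in unchanged_ids)
    if len(ids) <= n:
        if len(ids) < n:
            warnings.warn(f"only {len(ids)} unchanged events available; taking all "
                          f"(requested {n})")
        return ids
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(picked)]


def remove_score_outliers(scores, q: float = 0.005) -> tuple[np.ndarray, int]:
    """Trim values outside median +/- k*MAD, k set by the nominal rate q.

    ``k`` is the two-sided Gaussian quantile at which the expected
    false-removal rate on Gaussian data equals ``q`` (MAD scaled to estimate
    sigma consistently). Fewer than 5 values: nothing is removed.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 5:
        warnings.warn("fewer than 5 scores; outlier removal skipped")
        return scores, 0
    med = np.median(scores)
    mad = stats.median_abs_deviation(scores, scale="normal")
    k = stats.norm.ppf(1.0 - q / 2.0)
    keep = np.abs(scores - med) <= k * mad if mad > 0 else np.ones(scores.size, bool)
    return scores[keep], int(scores.size - keep.sum())


def compare_scores(scores_a, scores_b) -> tuple[float, float, float]:
    """Medians and two-sided rank-sum p for two score groups.

    Exact null distribution for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(res.pvalue)


def composition_per_intron(introns: list[IntronRecord]) -> pd.DataFrame:
    """Per-intron mean A/C/G/U frequency over py-tract positions -20..-3."""
    rows = [pytract_mean_frequencies(r.py_tract) for r in introns]
    return pd.DataFrame(rows, index=[r.name for r in introns], columns=list(BASES))


def compare_composition(introns_a: list[IntronRecord],
                        introns_b: list[IntronRecord]) -> ComparisonReport:
    """Per-base composition comparison between two intron groups.

    Computes each intron's mean base frequencies over the py tract, tests
    each base with a two-sided rank-sum test, and reports group mean
    profiles. Groups of fewer than 2 introns suppress the tests.
    """
    report = ComparisonReport(n_retained=len(introns_a), n_control=len(introns_b))
    if not introns_a or not introns_b:
        raise ValueError("both groups must be non-empty")
    fa = composition_per_intron(introns_a)
    fb = composition_per_intron(introns_b)
    suppress = len(introns_a) < 2 or len(introns_b) < 2
    for base in BASES:
        report.composition_means[base] = (float(fa[base].mean()), float(fb[base].mean()))
        if suppress:
            continue
        res = stats.mannwhitneyu(fa[base], fb[base], alternative="two-sided")
        report.composition_pvalues[base] = float(res.pvalue)
    if suppress:
        warnings.warn("a group has fewer than 2 introns; rank tests suppressed")
        report.tests_suppressed = True
    return report


def compare_retained_vs_control(events: pd.DataFrame,
                                introns: dict[str, IntronRecord],
                                scores: dict[str, dict[str, float]] | None = None,
                                cutoff: float = MV_DPSI_CUTOFF,
                                n_control: int = 500, seed: int = 0,
                                outlier_q: float | None = 0.005) -> ComparisonReport:
    """Full retained-vs-unaffected comparison over an event table.

    Parameters
    ----------
    events
        Event table with ``event_id``, ``dpsi``, ``mv_dpsi`` columns.
    introns
        Mapping event_id -> :class:`IntronRecord`; events without a sequence
        are excluded from composition comparisons and counted in the report.
    scores
        Optional precomputed site-strength columns, as
        ``{"5ss": {event_id: score}, "3ss": {...}}`` — e.g. externally
        computed maximum-entropy scores. When given, score comparisons are
        run with outlier trimming (set ``outlier_q=None`` to disable).
    """
    classified = select_events(events, cutoff)
    retained_ids = list(classified.loc[classified["class"] == "more_retained", "event_id"])
    unchanged_ids = list(classified.loc[classified["class"] == "unchanged", "event_id"])
    control_ids = sample_unaffected(unchanged_ids, n_control, seed)

    retained = [introns[e] for e in retained_ids if e in introns]
    control = [introns[e] for e in control_ids if e in introns]
    missing = (len(retained_ids) - len(retained)) + (len(control_ids) - len(control))

    report = compare_composition(retained, control)
    report.n_missing_sequence = missing

    if scores:
        for kind, table in scores.items():
            a = np.array([table[e] for e in retained_ids if e in table], dtype=float)
            b = np.array([table[e] for e in control_ids if e in table], dtype=float)
            removed = 0
            if outlier_q is not None:
                a, ra = remove_score_outliers(a, outlier_q)
                b, rb = remove_score_outliers(b, outlier_q)
                removed = ra + rb
            med_a, med_b, p = compare_scores(a, b)
            report.score_medians[kind] = (med_a, med_b)
            report.score_pvalues[kind] = p
            report.outliers_removed += removed
    return report
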