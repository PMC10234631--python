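"""Splice-site windows, position frequency matrices, logos, and site scoring.

Window conventions (transcript orientation, positions in the field's standard
labelling where the G of the 3' splice-site AG is position -1):

* 5'SS: 9 nt, exon -3..-1 followed by intron +1..+6;
* 3'SS: 23 nt, intron -20..-1 followed by exon +1..+3;
* py tract: 18 nt, intron -20..-3 (the first 18 characters of the 3'SS).

Windows are emitted with the lowercase-intron / uppercase-exon convention.
Genomic intervals are BED-style 0-based half-open on the forward strand;
minus-strand introns are reverse-complemented into transcript orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from foxsplice.config import ALPHABET

log = logging.getLogger(__name__)

FIVE_SS_LEN = 9
THREE_SS_LEN = 23
PY_TRACT_LEN = 18
EXON_FLANK = 3
#: minimum intron length able to host disjoint donor (+1..+6) and acceptor (-20..-1) windows
MIN_INTRON_LEN = 26

FIVE_SS_POSITIONS = [-3, -2, -1, 1, 2, 3, 4, 5, 6]
THREE_SS_POSITIONS = list(range(-20, 0)) + [1, 2, 3]
PY_TRACT_POSITIONS = list(range(-20, -2))

_DISPLAY = {"T": "U"}  # internal alphabet is DNA; displays report U


@dataclass
class IntronRecord:
    """One intron's coordinates plus its splice-site windows.

    ``start``/``end`` are 0-based half-open on the forward genome strand;
    windows are stored in transcript orientation.
    """

    gene_id: str
    intron_index: int
    chrom: str
    start: int
    end: int
    strand: str
    five_ss: str
    three_ss: str
    py_tract: str
    canonical: bool = True

    def __post_init__(self) -> None:
        if len(self.five_ss) != FIVE_SS_LEN:
            raise ValueError(f"five_ss must be {FIVE_SS_LEN} nt, got {len(self.five_ss)}")
        if len(self.three_ss) != THREE_SS_LEN:
            raise ValueError(f"three_ss must be {THREE_SS_LEN} nt, got {len(self.three_ss)}")
        if self.py_tract != self.three_ss[:PY_TRACT_LEN]:
            raise ValueError("py_tract must equal the first 18 characters of three_ss")

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.intron_index}"


def make_windows(exon_left: str, intron: str, exon_right: str) -> tuple[str, str, str, bool]:
    """Build (five_ss, three_ss, py_tract, canonical) from transcript-oriented parts."""
    if len(exon_left) < EXON_FLANK or len(exon_right) < EXON_FLANK:
        raise ValueError("need at least 3 nt of exonic flank on each side")
    if len(intron) < MIN_INTRON_LEN:
        raise ValueError(f"intron shorter than {MIN_INTRON_LEN} nt")
    five_ss = exon_left[-EXON_FLANK:].upper() + intron[:6].lower()
    three_ss = intron[-20:].lower() + exon_right[:EXON_FLANK].upper()
    py_tract = three_ss[:PY_TRACT_LEN]
    canonical = intron[:2].lower() == "gt" and intron[-2:].lower() == "ag"
    return five_ss, three_ss, py_tract, canonical


def _chrom_seq(genome, chrom: str) -> str:
    seq = genome[chrom]
    return str(seq[:])  # pyfaidx FastaRecord and plain str both support [:]


def extract_splice_sites(genome, intervals: Iterable[Sequence]) -> list[IntronRecord]:
    """Extract splice-site windows for each intron interval.

    Parameters
    ----------
    genome
        Mapping from chromosome name to sequence; a ``pyfaidx.Fasta`` object
        or a plain ``dict`` of strings.
    intervals
        BED6-like rows ``(chrom, start, end, name, score, strand)`` with
        ``name`` formatted ``gene_id|intron_index`` (a bare name is taken as
        the gene id with index 0).

    Out-of-bounds or too-short intervals are skipped and logged, never fatal.
    """
    records: list[IntronRecord] = []
    for row in intervals:
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if len(row) > 3 else f"{chrom}:{start}-{end}"
        strand = str(row[5]) if len(row) > 5 else "+"
        gene_id, _, idx = name.partition("|")
        intron_index = int(idx) if idx else 0
        try:
            seq = _chrom_seq(genome, chrom)
        except KeyError:
            log.warning("skipping %s: unknown chromosome %s", name, chrom)
            continue
        if start < EXON_FLANK or end + EXON_FLANK > len(seq) or end - start < MIN_INTRON_LEN:
            log.warning("skipping %s: interval %s:%d-%d lacks flank or is too short",
                        name, chrom, start, end)
            continue
        intron = seq[start:end]
        left = seq[start - EXON_FLANK:start]
        right = seq[end:end + EXON_FLANK]
        if strand == "-":
            intron, left, right = (reverse_complement(intron),
                                   reverse_complement(right),
                                   reverse_complement(left))
        five_ss, three_ss, py_tract, canonical = make_windows(left, intron, right)
        records.append(IntronRecord(gene_id, intron_index, chrom, start, end, strand,
                                    five_ss, three_ss, py_tract, canonical))
    return records


# ---------------------------------------------------------------------------
# position frequency matrices and logo math


@dataclass
class PositionFrequencyMatrix:
    """Column-stochastic per-position base probabilities over {A, C, G, U}."""

    positions: list
    probs: np.ndarray  # shape (L, 4), rows sum to 1
    n_sequences: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.positions), len(ALPHABET)):
            raise ValueError("probs shape does not match positions")
        if (self.probs < 0).any() or not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must be non-negative and sum to 1")

    def to_frame(self) -> pd.DataFrame:
        cols = [_DISPLAY.get(b, b) for b in ALPHABET]
        return pd.DataFrame(self.probs, index=self.positions, columns=cols)

    def mean_frequencies(self) -> dict[str, float]:
        """Base frequencies averaged over positions, keyed A/C/G/U."""
        means = self.probs.mean(axis=0)
        return {_DISPLAY.get(b, b): float(m) for b, m in zip(ALPHABET, means)}


_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_BASE_INDEX["U"] = _BASE_INDEX["T"]


def _count_matrix(sequences: Sequence[str], length: int) -> tuple[np.ndarray, int]:
    counts = np.zeros((length, len(ALPHABET)), dtype=float)
    kept = 0
    for seq in sequences:
        s = seq.upper()
        if len(s) != length:
            raise ValueError(f"all sequences must have length {length}, got {len(s)}")
        n_amb = sum(1 for ch in s if ch not in _BASE_INDEX)
        if n_amb > 0.10 * length:
            warnings.warn(f"rejecting sequence with >10% ambiguous bases: {seq!r}")
            continue
        for pos, ch in enumerate(s):
            idx = _BASE_INDEX.get(ch)
            if idx is not None:  # N and other ambiguity codes leave the column denominator
                counts[pos, idx] += 1
        kept += 1
    return counts, kept


def position_frequency(sequences: Sequence[str],
                       positions: Sequence | None = None) -> PositionFrequencyMatrix:
    """Per-position base probabilities of an equal-length sequence set.

    Ambiguous bases (N) are excluded from the column denominators; sequences
    with more than 10% ambiguous characters are rejected with a warning.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("cannot build a frequency matrix from an empty sequence set")
    length = len(sequences[0])
    counts, kept = _count_matrix(sequences, length)
    if kept == 0:
        raise ValueError("all sequences were rejected")
    denom = counts.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    if positions is None:
        positions = list(range(length))
    return PositionFrequencyMatrix(list(positions), counts / denom, kept)


def gene_average_pfm(introns: Sequence[IntronRecord],
                     window: str = "py_tract") -> PositionFrequencyMatrix:
    """Average py-tract (or splice-site) base probabilities over one gene's introns.

    Each intron contributes one indicator column per position, so the average
    equals the pooled per-position frequency with every intron counted once.
    """
    if not introns:
        raise ValueError("gene has no introns")
    positions = {"py_tract": PY_TRACT_POSITIONS,
                 "five_ss": FIVE_SS_POSITIONS,
                 "three_ss": THREE_SS_POSITIONS}[window]
    seqs = [getattr(r, window) for r in introns]
    return position_frequency(seqs, positions=positions)


def information_content(pfm: PositionFrequencyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-position information content in bits and the logo letter-height matrix.

    ``IC = 2 + sum_b p log2 p`` with ``0 log 0 := 0``; letter height is
    ``p * IC``. No small-sample correction is applied, so IC is bounded by
    [0, 2] bits exactly.
    """
    p = pfm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, 2.0)
    return ic, p * ic[:, None]


def pytract_mean_frequencies(sequence: str) -> dict[str, float]:
    """Mean A/C/G/U frequency of a single py-tract sequence."""
    pfm = position_frequency([sequence])
    return pfm.mean_frequencies()


def classify_py_tract(data) -> tuple[str, dict[str, float]]:
    """Classify a py tract (or set) as C-rich, U-rich, or neither.

    Accepts a single sequence, a sequence set, or a
    :class:`PositionFrequencyMatrix`. The decision rule is the sign of
    ``mean C - mean U`` over positions -20..-3; an exact tie is ``neither``.
    """
    if isinstance(data, PositionFrequencyMatrix):
        pfm = data
    elif isinstance(data, str):
        pfm = position_frequency([data])
    else:
        pfm = position_frequency(list(data))
    freqs = pfm.mean_frequencies()
    if freqs["C"] > freqs["U"]:
        label = "C-rich"
    elif freqs["U"] > freqs["C"]:
        label = "U-rich"
    else:
        label = "neither"
    return label, freqs


# ---------------------------------------------------------------------------
# weight-matrix splice-site strength scoring


@dataclass
class SpliceScoreModel:
    """Position weight-matrix log-odds site scorer (bits).

    A monotone site-strength score standing behind the same interface as an
    externally computed maximum-entropy score column: per-position
    ``log2(p(b) / background(b))`` summed over the window.
    """

    site_kind: str  # "5ss" or "3ss"
    score_table: np.ndarray  # (L, 4) log-odds in bits
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    @property
    def length(self) -> int:
        return self.score_table.shape[0]


def train_wmm(training_sites: Sequence[str], site_kind: str,
              background: Sequence[float] | None = None,
              pseudocount: float = 0.5) -> SpliceScoreModel:
    """Fit a position weight matrix from aligned splice-site windows."""
    expected_len = {"5ss": FIVE_SS_LEN, "3ss": THREE_SS_LEN}.get(site_kind)
    if expected_len is None:
        raise ValueError(f"site_kind must be '5ss' or '3ss', got {site_kind!r}")
    sites = list(training_sites)
    if not sites:
        raise ValueError("need at least one training site")
    if any(len(s) != expected_len for s in sites):
        raise ValueError(f"all {site_kind} training windows must be {expected_len} nt")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a length-4 probability vector")
    counts, kept = _count_matrix(sites, expected_len)
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        table = np.log2(probs / bg)
    return SpliceScoreModel(site_kind, table, bg, pseudocount)


def score_site(model: SpliceScoreModel, window: str, strict: bool = False) -> float:
    """Score a window under a weight matrix: sum of per-position bit contributions.

    Non-ACGT characters are skipped with a warning, or raise in strict mode.
    """
    w = window.upper()
    if len(w) != model.length:
        raise ValueError(f"window length {len(w)} does not match model length {model.length}")
    total = 0.0
    for pos, ch in enumerate(w):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            if strict:
                raise ValueError(f"non-ACGT character {ch!r} at position {pos}")
            warnings.warn(f"skipping non-ACGT character {ch!r} at position {pos}")
            continue
        total += float(model.score_table[pos, idx])
    return total
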