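"""Resampling overlap enrichment between a DEG set and a target gene set.

The observed overlap ``k`` between ``n1`` DEGs and ``n2`` target genes inside
a universe of ``N`` expressed genes is compared against a null built by
repeatedly resampling ``n1`` genes uniformly without replacement from the
universe and counting the overlap with the target set; the empirical p is the
fraction of resamples with overlap >= k, reported as the raw fraction (with a
"< 1/R" floor flag when no resample reaches k). Because sampling is without
replacement, the exact null is hypergeometric, which serves as the closed-form
oracle for every Monte Carlo result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

DEFAULT_R = 100_000


@dataclass
class EnrichmentResult:
    """Observed overlap, resampling-null summary, empirical and exact p."""

    N: int
    n1: int
    n2: int
    k: int
    R: int
    null_counts: np.ndarray  # histogram over overlap values 0..min(n1, n2)
    null_mode: int
    empirical_p: float
    exact_p: float
    seed: int
    label: str = ""

    @property
    def empirical_p_str(self) -> str:
        """Raw fraction, with the honest floor when no resample reached k."""
        return f"< {1.0 / self.R:g}" if self.empirical_p == 0.0 else f"{self.empirical_p:g}"

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in
             ("label", "N", "n1", "n2", "k", "R", "null_mode", "empirical_p", "exact_p", "seed")}
        d["empirical_p_str"] = self.empirical_p_str
        d["null_counts"] = np.asarray(self.null_counts).tolist()
        return d


def observed_overlap(deg_set: Iterable[str], target_set: Iterable[str],
                     universe: Iterable[str]) -> tuple[int, int, int, int]:
    """Restrict both sets to the universe and count (N, n1, n2, k).

    Restriction mirrors keeping only target genes detected in the expression
    data before testing for enrichment.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    degs = set(deg_set) & universe
    target = set(target_set) & universe
    return len(universe), len(degs), len(target), len(degs & target)


def resample_null(N: int, n1: int, n2: int, R: int = DEFAULT_R,
                  seed: int = 0) -> np.ndarray:
    """Histogram of overlap counts over R without-replacement resamples.

    Each resample draws ``n1`` genes uniformly without replacement from a
    universe of ``N`` containing ``n2`` marked genes. Draws are realized by
    ranking i.i.d. uniform keys: the ``n1`` smallest keys form the sample, and
    the overlap is the number of marked genes among them.
    """
    for name, v in (("N", N), ("n1", n1), ("n2", n2)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n1 > N or n2 > N:
        raise ValueError(f"sample sizes (n1={n1}, n2={n2}) cannot exceed the universe N={N}")
    if R < 1:
        raise ValueError("R must be at least 1")

    max_overlap = min(n1, n2)
    counts = np.zeros(max_overlap + 1, dtype=np.int64)
    if n1 == 0 or n2 == 0:
        counts[0] = R
        return counts
    if n1 == N:
        counts[max_overlap] = R  # every draw takes the whole universe
        return counts

    rng = np.random.default_rng(seed)
    chunk = max(1, 8_000_000 // N)  # bounded scratch memory
    done = 0
    while done < R:
        m = min(chunk, R - done)
        keys = rng.random((m, N))
        kth = np.partition(keys, n1 - 1, axis=1)[:, n1 - 1]
        overlap = (keys[:, :n2] <= kth[:, None]).sum(axis=1)
        counts += np.bincount(np.minimum(overlap, max_overlap), minlength=max_overlap + 1)
        done += m
    return counts


def empirical_p(null_counts: np.ndarray, k: int) -> float:
    """Fraction of null resamples with overlap >= k (raw, unshifted)."""
    counts = np.asarray(null_counts)
    if counts.sum() == 0:
        raise ValueError("null histogram is empty")
    if k <= 0:
        return 1.0
    if k >= len(counts):
        return 0.0
    return float(counts[k:].sum() / counts.sum())


def null_mode(null_counts: np.ndarray) -> int:
    """Most frequent overlap value in the resampling null (smallest on ties)."""
    return int(np.argmax(np.asarray(null_counts)))


def hypergeom_tail(N: int, n1: int, n2: int, k: int) -> float:
    """Exact upper-tail P(overlap >= k) under without-replacement sampling.

    Closed-form oracle for :func:`resample_null`; evaluated in log space by
    the hypergeometric survival function.
    """
    for name, v in (("N", N), ("n1", n1), ("n2", n2), ("k", k)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n1 > N or n2 > N:
        raise ValueError("sample sizes cannot exceed the universe")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n2, n1))


def enrich(deg_set: Iterable[str], target_set: Iterable[str], universe: Iterable[str],
           R: int = DEFAULT_R, seed: int = 0, label: str = "") -> EnrichmentResult:
    """Run the full overlap test: observed counts, resampling null, both p values."""
    N, n1, n2, k = observed_overlap(deg_set, target_set, universe)
    counts = resample_null(N, n1, n2, R, seed)
    return EnrichmentResult(
        N=N, n1=n1, n2=n2, k=k, R=R,
        null_counts=counts,
        null_mode=null_mode(counts),
        empirical_p=empirical_p(counts, k),
        exact_p=hypergeom_tail(N, n1, n2, k),
        seed=seed, label=label,
    )


def directional_enrichment(up_set: Iterable[str], down_set: Iterable[str],
                           pathogenic_set: Iterable[str], protective_set: Iterable[str],
                           universe: Iterable[str], R: int = DEFAULT_R,
                           seed: int = 0) -> dict[str, EnrichmentResult]:
    """The four directional contrasts: concordant pairings and their flips.

    Every contrast uses the same resampling seed, so symmetric inputs yield
    identical results across the four.
    """
    contrasts = {
        "up_pathogenic": (up_set, pathogenic_set),
        "down_protective": (down_set, protective_set),
        "up_protective": (up_set, protective_set),
        "down_pathogenic": (down_set, pathogenic_set),
    }
    return {name: enrich(degs, target, universe, R, seed, label=name)
            for name, (degs, target) in contrasts.items()}
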