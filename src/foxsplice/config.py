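"""Simulation and pipeline configuration objects.

``SimulationConfig`` carries every parameter of the synthetic-data module:
library-scale expression parameters, the spiked DEG fraction and effect size,
the SNP-gene pair table structure (odds-ratio / effect-size sign structure and
missingness), per-position py-tract base profiles, and the logistic link
between py-tract C content and intron retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

#: Column order of every per-position base-probability vector.
ALPHABET = ("A", "C", "G", "T")

PY_TRACT_LEN = 18


class InvalidConfigError(ValueError):
    """A configuration value violates its documented constraint."""


def _uniform_profile(weights: Mapping[str, float]) -> np.ndarray:
    """Tile one probability vector over the 18 py-tract positions."""
    row = np.array([weights[b] for b in ALPHABET], dtype=float)
    return np.tile(row, (PY_TRACT_LEN, 1))


def crich_profile(c: float = 0.5, u: float = 0.2) -> np.ndarray:
    """C-rich py-tract profile: P(C)=c, P(U)=u, remainder split A/G."""
    rest = (1.0 - c - u) / 2.0
    return _uniform_profile({"A": rest, "C": c, "G": rest, "T": u})


def urich_profile(u: float = 0.5, c: float = 0.2) -> np.ndarray:
    """U-rich py-tract profile: the mirror of :func:`crich_profile`."""
    rest = (1.0 - c - u) / 2.0
    return _uniform_profile({"A": rest, "C": c, "G": rest, "T": u})


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-data generators.

    Defaults are the study conditions the downstream analyses assume: two
    donors with a spiked 5% DEG fraction at |log-fold| effect 1.0, a 500-gene
    susceptibility pair table with balanced pathogenic/protective direction and
    5% missing eQTL effect sizes, and 900 introns whose retention probability
    follows ``logit p = retention_intercept + retention_slope * C-fraction``.
    """

    seed: int = 0
    # expression table
    n_genes: int = 10_000
    n_donors: int = 2
    deg_fraction: float = 0.05
    deg_effect: float = 1.0
    nondeg_score_sd: float = 0.05
    rpkm_log_mean: float = 1.0
    rpkm_log_sd: float = 1.0
    # SNP-gene susceptibility pairs
    n_ms_genes: int = 500
    frac_pathogenic: float = 0.5
    frac_missing_nes: float = 0.05
    # introns and retention
    n_introns: int = 900
    pytract_profile_crich: np.ndarray = field(default_factory=crich_profile)
    pytract_profile_urich: np.ndarray = field(default_factory=urich_profile)
    retention_slope: float = 6.0
    retention_intercept: float = -3.0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_donors": self.n_donors,
            "n_ms_genes": self.n_ms_genes,
            "n_introns": self.n_introns,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise InvalidConfigError(f"{name} must be a positive integer, got {value!r}")
        fractions = {
            "deg_fraction": self.deg_fraction,
            "frac_pathogenic": self.frac_pathogenic,
            "frac_missing_nes": self.frac_missing_nes,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("pytract_profile_crich", "pytract_profile_urich"):
            profile = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, profile)
            if profile.shape != (PY_TRACT_LEN, len(ALPHABET)):
                raise InvalidConfigError(
                    f"{name} must have shape ({PY_TRACT_LEN}, {len(ALPHABET)}), got {profile.shape}"
                )
            if (profile < 0).any():
                raise InvalidConfigError(f"{name} contains negative probabilities")
            if not np.allclose(profile.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidConfigError(f"{name} rows must each sum to 1 within 1e-9")
        if self.rpkm_log_sd < 0 or self.nondeg_score_sd < 0 or self.deg_effect < 0:
            raise InvalidConfigError("scale parameters must be non-negative")

    def profile(self, kind: str) -> np.ndarray:
        """Return the py-tract profile named ``crich`` or ``urich``."""
        try:
            return {"crich": self.pytract_profile_crich,
                    "urich": self.pytract_profile_urich}[kind]
        except KeyError:
            raise InvalidConfigError(f"unknown py-tract profile {kind!r}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pytract_profile_crich"] = self.pytract_profile_crich.tolist()
        d["pytract_profile_urich"] = self.pytract_profile_urich.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("pytract_profile_crich", "pytract_profile_urich"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage integer seed (< 2**31) from one master seed.

    A single pipeline seed expands deterministically into independent
    per-stage seeds so that toggling one stage never perturbs another.
    """
    h = np.uint64(0xCBF29CE484222325)  # FNV-1a over the stage name, mixed with the seed
    with np.errstate(over="ignore"):
        for ch in stage.encode():
            h = np.uint64(h ^ np.uint64(ch)) * np.uint64(0x100000001B3)
        h = h ^ np.uint64(master_seed & 0xFFFFFFFFFFFF)
        h = h * np.uint64(0x100000001B3)
    return int(h % np.uint64(2**31 - 1))
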