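"""Capped log10-odds (LOD) comparison of two fingerprints.

Per block the likelihood-ratio term is

    log10[ sum_g Lx(g) Ly(g) p(g) / (sum_g Lx(g) p(g) * sum_h Ly(h) p(h)) ]

with Hardy-Weinberg genotype priors p(g) from the block's anchor MAF, then
floored at ``cap_sigma`` so a single discordant locus cannot dominate. The
total LOD is the sum over blocks plus log10 of the prior odds (applied once,
as a constant shift). Positive totals favour a shared donor.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from ._util import log10sumexp
from .errors import ChecksumMismatchError, ConfigurationError
from .fingerprinting import BlockLikelihoods, Fingerprint
from .haplotype_map import HaplotypeMap


class Classification(enum.Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class GenotypePrior:
    """Hardy-Weinberg genotype prior from a minor-allele frequency."""

    p_aa: float
    p_ab: float
    p_bb: float

    def __post_init__(self):
        total = self.p_aa + self.p_ab + self.p_bb
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(f"genotype prior sums to {total}, not 1")
        if min(self.p_aa, self.p_ab, self.p_bb) < 0:
            raise ConfigurationError("genotype prior probabilities must be >= 0")

    @classmethod
    def from_maf(cls, maf: float) -> "GenotypePrior":
        if not 0.0 < maf <= 0.5:
            raise ConfigurationError(f"maf must be in (0, 0.5], got {maf}")
        return cls((1 - maf) ** 2, 2 * maf * (1 - maf), maf * maf)

    @property
    def array(self) -> np.ndarray:
        return np.array([self.p_aa, self.p_ab, self.p_bb])


@dataclass(frozen=True)
class ScoringConfig:
    """Prior odds p(same)/p(different), per-block floor, decision bound."""

    prior_odds: float = 1.0
    cap_sigma: float = -3.0
    decision_threshold: float = 5.0

    def __post_init__(self):
        if self.prior_odds <= 0:
            raise ConfigurationError("prior_odds must be positive")
        if self.cap_sigma >= 0:
            raise ConfigurationError("cap_sigma must be negative")
        if self.decision_threshold <= 0:
            raise ConfigurationError("decision_threshold must be positive")


@dataclass
class LODReport:
    """Outcome of comparing two fingerprints."""

    left_sample: str
    right_sample: str
    lod: float
    per_block: dict[str, float]
    n_informative: int
    classification: Classification

    def __repr__(self) -> str:
        return (f"LODReport({self.left_sample} vs {self.right_sample}: "
                f"LOD={self.lod:.3f}, {self.classification.value}, "
                f"{self.n_informative} informative blocks)")


def block_lod_term(
    bx: BlockLikelihoods,
    by: BlockLikelihoods,
    prior: GenotypePrior,
    cap_sigma: float = -3.0,
) -> float:
    """Capped per-block log10 likelihood-ratio term (prior odds excluded).

    A block where either side has no observations contributes exactly 0:
    with a flat likelihood the ratio is identically 1.
    """
    if bx.n_observations == 0 or by.n_observations == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        lp = np.log10(prior.array)
    lx = bx.array
    ly = by.array
    num = log10sumexp(lx + ly + lp)
    den = log10sumexp(lx + lp) + log10sumexp(ly + lp)
    term = num - den
    if not np.isfinite(term):
        term = -math.inf
    return max(float(term), cap_sigma)


def _priors_for_map(hmap: HaplotypeMap) -> np.ndarray:
    """(n_blocks, 3) log10 HWE priors from each block's anchor MAF."""
    mafs = np.array([b.block_maf for b in hmap.blocks])
    if np.any(mafs <= 0):
        raise ConfigurationError("all block MAFs must be positive for scoring")
    p = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2], axis=1)
    return np.log10(p)


def total_lod(
    fx: Fingerprint,
    fy: Fingerprint,
    hmap: HaplotypeMap,
    cfg: ScoringConfig = ScoringConfig(),
) -> LODReport:
    """Genome-wide capped LOD between two fingerprints bound to one map."""
    checksum = hmap.checksum
    for fp in (fx, fy):
        if fp.map_checksum != checksum:
            raise ChecksumMismatchError(
                f"fingerprint {fp.sample_id} is bound to a different map"
            )
    lp = _priors_for_map(hmap)
    lx, ly = fx.ll, fy.ll
    num = log10sumexp(lx + ly + lp, axis=1)
    den = log10sumexp(lx + lp, axis=1) + log10sumexp(ly + lp, axis=1)
    with np.errstate(invalid="ignore"):
        terms = num - den
    informative = (fx.n_obs > 0) & (fy.n_obs > 0)
    terms = np.where(informative, terms, 0.0)
    terms = np.where(np.isnan(terms), -np.inf, terms)
    terms = np.maximum(terms, cfg.cap_sigma)
    lod = float(terms.sum()) + math.log10(cfg.prior_odds)
    return LODReport(
        left_sample=fx.sample_id,
        right_sample=fy.sample_id,
        lod=lod,
        per_block=dict(zip(fx.anchor_names, terms.tolist())),
        n_informative=int(informative.sum()),
        classification=classify(lod, cfg.decision_threshold),
    )


def shift_for_prior(lod: float, prior_odds: float) -> float:
    """Shift a prior-1 LOD by log10 of the desired prior odds."""
    if prior_odds <= 0:
        raise ConfigurationError("prior_odds must be positive")
    return lod + math.log10(prior_odds)


def classify(lod: float, threshold: float = 5.0) -> Classification:
    """>= threshold: MATCH; <= -threshold: MISMATCH; else INCONCLUSIVE.

    Exactly +/- threshold is conclusive.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    if lod >= threshold:
        return Classification.MATCH
    if lod <= -threshold:
        return Classification.MISMATCH
    return Classification.INCONCLUSIVE
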