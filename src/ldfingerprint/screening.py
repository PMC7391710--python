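"""Database-scale swap screening.

Each screened dataset is compared only to its nominal donor's three
representative datasets (highest self-LOD, repaired to mutual
consistency), so the comparison count grows linearly with database size.
Flagged datasets are compared to every donor's representatives to
nominate a true donor, and cross-donor representative comparisons expose
duplicate-donor accessions.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InsufficientReadsError
from .fingerprinting import Fingerprint, ReadFilterConfig, build_fingerprint
from .haplotype_map import HaplotypeMap
from .lod_scoring import ScoringConfig, total_lod

logger = logging.getLogger(__name__)

#: a donor needs this many datasets to be screenable (3 representatives
#: plus at least one replacement candidate)
MIN_DATASETS_PER_DONOR = 4


class Status(enum.Enum):
    CONFIRMED = "CONFIRMED"
    SWAP_FLAGGED = "SWAP_FLAGGED"
    INCONCLUSIVE = "INCONCLUSIVE"
    UNSCREENABLE = "UNSCREENABLE"
    MANUAL_REVIEW = "MANUAL_REVIEW"


@dataclass(frozen=True)
class ManifestEntry:
    dataset_id: str
    donor: str
    path: str = ""


@dataclass
class Manifest:
    entries: list[ManifestEntry]

    def __post_init__(self):
        ids = [e.dataset_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("dataset_ids in manifest must be unique")

    @classmethod
    def from_tsv(cls, path) -> "Manifest":
        """TSV with header DATASET_ID, DONOR, PATH."""
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["DATASET_ID", "DONOR", "PATH"]
            if header[: len(expected)] != expected:
                raise ConfigurationError(
                    f"manifest header must start with {expected}, got {header}"
                )
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                entries.append(ManifestEntry(fields[0], fields[1],
                                             fields[2] if len(fields) > 2 else ""))
        return cls(entries)

    def by_donor(self) -> dict[str, list[ManifestEntry]]:
        out: dict[str, list[ManifestEntry]] = {}
        for e in self.entries:
            out.setdefault(e.donor, []).append(e)
        return out


@dataclass
class RepresentativeSet:
    donor: str
    members: list[str]  # dataset ids, empty if manual review
    status: str  # "OK" | "MANUAL_REVIEW"
    n_comparisons: int = 0


@dataclass
class ScreeningReport:
    statuses: dict[str, Status]
    min_lod_vs_reps: dict[str, float]
    nominations: dict[str, list[tuple[str, float]]]  # flagged id -> ranked donors
    clusters: list[list[str]]  # duplicate-donor clusters
    representatives: dict[str, RepresentativeSet]
    pairwise_lods: list[tuple[str, str, float]]
    n_comparisons: int = 0
    #: comparisons used for screening proper (reps + 3 per dataset), before
    #: donor nomination and the cross-donor duplicate check
    n_screening_comparisons: int = 0

    def to_tsv(self, path, manifest: Manifest) -> None:
        from ._util import atomic_write

        with atomic_write(path) as fh:
            fh.write("DATASET_ID\tDONOR\tSTATUS\tMIN_LOD_VS_REPS\tNOMINATED_DONOR\n")
            for e in manifest.entries:
                status = self.statuses.get(e.dataset_id, Status.UNSCREENABLE)
                min_lod = self.min_lod_vs_reps.get(e.dataset_id)
                nominated = self.nominations.get(e.dataset_id) or []
                fh.write(
                    f"{e.dataset_id}\t{e.donor}\t{status.value}\t"
                    f"{'' if min_lod is None else f'{min_lod:.4f}'}\t"
                    f"{','.join(d for d, _ in nominated)}\n"
                )


class _LodCache:
    """Memoized pairwise LOD computation with a comparison counter."""

    def __init__(self, fingerprints: Mapping[str, Fingerprint],
                 hmap: HaplotypeMap, cfg: ScoringConfig):
        self.fps = fingerprints
        self.hmap = hmap
        self.cfg = cfg
        self.cache: dict[tuple[str, str], float] = {}
        self.n_comparisons = 0

    def lod(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self.cache:
            self.cache[key] = total_lod(self.fps[a], self.fps[b],
                                        self.hmap, self.cfg).lod
            self.n_comparisons += 1
        return self.cache[key]


def self_lod(
    fp: Fingerprint, hmap: HaplotypeMap, cfg: ScoringConfig = ScoringConfig()
) -> float:
    """LOD of a dataset against itself: a proxy for informative map overlap."""
    return total_lod(fp, fp, hmap, cfg).lod


def select_representatives(
    donor_datasets: Mapping[str, Fingerprint],
    hmap: HaplotypeMap,
    cfg: ScoringConfig = ScoringConfig(),
    _cache: "_LodCache | None" = None,
) -> RepresentativeSet:
    """Pick the three highest self-LOD datasets and repair to consistency.

    A triplet is self-consistent when all three pairwise LODs are at or
    above the decision threshold. The single-swap pattern (one member
    mismatching both others while the remaining pair matches) is repaired
    by substituting the next-highest self-LOD candidate; any other
    inconsistency, or pool exhaustion, yields MANUAL_REVIEW.
    """
    if len(donor_datasets) < MIN_DATASETS_PER_DONOR:
        raise ConfigurationError(
            f"representative selection needs >= {MIN_DATASETS_PER_DONOR} datasets"
        )
    cache = _cache or _LodCache(dict(donor_datasets), hmap, cfg)
    ranked = sorted(
        donor_datasets,
        key=lambda ds: (-self_lod(donor_datasets[ds], hmap, cfg), ds),
    )
    current = ranked[:3]
    pool = ranked[3:]
    thr = cfg.decision_threshold
    while True:
        a, b, c = current
        lods = {
            (a, b): cache.lod(a, b),
            (a, c): cache.lod(a, c),
            (b, c): cache.lod(b, c),
        }
        if all(v >= thr for v in lods.values()):
            return RepresentativeSet("", list(current), "OK", cache.n_comparisons)
        # single-swap pattern: exactly one member mismatches both others
        # (LOD <= -thr) while the remaining pair is a conclusive match
        culprit = None
        for member in current:
            mine = [v for pair, v in lods.items() if member in pair]
            others = [v for pair, v in lods.items() if member not in pair]
            if all(v <= -thr for v in mine) and all(v >= thr for v in others):
                if culprit is not None:
                    culprit = None
                    break
                culprit = member
        if culprit is None or not pool:
            return RepresentativeSet("", [], "MANUAL_REVIEW", cache.n_comparisons)
        current = [m for m in current if m != culprit] + [pool.pop(0)]


def screen(
    manifest: Manifest,
    fingerprints: Mapping[str, Fingerprint],
    hmap: HaplotypeMap,
    cfg: ScoringConfig = ScoringConfig(),
) -> ScreeningReport:
    """Screen every dataset against its donor's representative triplet.

    SWAP_FLAGGED if any of the three LODs is a conclusive mismatch (this
    takes precedence), INCONCLUSIVE if any falls inside the open interval
    (-threshold, threshold), CONFIRMED otherwise. Donors with fewer than
    four datasets are UNSCREENABLE.
    """
    cache = _LodCache(dict(fingerprints), hmap, cfg)
    thr = cfg.decision_threshold
    statuses: dict[str, Status] = {}
    min_lods: dict[str, float] = {}
    representatives: dict[str, RepresentativeSet] = {}

    for donor, entries in manifest.by_donor().items():
        ids = [e.dataset_id for e in entries]
        if len(ids) < MIN_DATASETS_PER_DONOR:
            for ds in ids:
                statuses[ds] = Status.UNSCREENABLE
            continue
        reps = select_representatives(
            {ds: fingerprints[ds] for ds in ids}, hmap, cfg, _cache=cache
        )
        reps.donor = donor
        representatives[donor] = reps
        if reps.status == "MANUAL_REVIEW":
            for ds in ids:
                statuses[ds] = Status.MANUAL_REVIEW
            continue
        for ds in ids:
            if ds in reps.members:
                statuses[ds] = Status.CONFIRMED
                continue
            lods = [cache.lod(ds, rep) for rep in reps.members]
            min_lods[ds] = min(lods)
            if any(v <= -thr for v in lods):
                statuses[ds] = Status.SWAP_FLAGGED
            elif any(-thr < v < thr for v in lods):
                statuses[ds] = Status.INCONCLUSIVE
            else:
                statuses[ds] = Status.CONFIRMED

    n_screening = cache.n_comparisons
    rep_fps = {
        donor: {ds: fingerprints[ds] for ds in reps.members}
        for donor, reps in representatives.items()
        if reps.status == "OK"
    }
    nominations: dict[str, list[tuple[str, float]]] = {}
    for ds, status in statuses.items():
        if status is Status.SWAP_FLAGGED:
            nominations[ds] = nominate_donor(
                fingerprints[ds], rep_fps, hmap, cfg, _cache=cache,
                _flagged_id=ds,
            )
    clusters = cross_donor_check(rep_fps, hmap, cfg, _cache=cache)
    pairwise = [(a, b, v) for (a, b), v in cache.cache.items()]
    return ScreeningReport(
        statuses=statuses,
        min_lod_vs_reps=min_lods,
        nominations=nominations,
        clusters=clusters,
        representatives=representatives,
        pairwise_lods=pairwise,
        n_comparisons=cache.n_comparisons,
        n_screening_comparisons=n_screening,
    )


def nominate_donor(
    flagged_fp: Fingerprint,
    all_representatives: Mapping[str, Mapping[str, Fingerprint]],
    hmap: HaplotypeMap,
    cfg: ScoringConfig = ScoringConfig(),
    _cache: "_LodCache | None" = None,
    _flagged_id: str | None = None,
) -> list[tuple[str, float]]:
    """Rank donors whose representatives all conclusively match the
    flagged fingerprint; highest minimum LOD first. Empty if none qualify."""
    thr = cfg.decision_threshold
    qualifying: list[tuple[str, float]] = []
    for donor, reps in all_representatives.items():
        lods = []
        for rep_id, rep_fp in reps.items():
            if _cache is not None and _flagged_id is not None:
                lods.append(_cache.lod(_flagged_id, rep_id))
            else:
                lods.append(total_lod(flagged_fp, rep_fp, hmap, cfg).lod)
        if lods and min(lods) >= thr:
            qualifying.append((donor, min(lods)))
    return sorted(qualifying, key=lambda t: (-t[1], t[0]))


def cross_donor_check(
    all_representatives: Mapping[str, Mapping[str, Fingerprint]],
    hmap: HaplotypeMap,
    cfg: ScoringConfig = ScoringConfig(),
    _cache: "_LodCache | None" = None,
) -> list[list[str]]:
    """Single-linkage clusters of donors joined by any conclusive positive
    LOD between their representatives; only clusters of size > 1 reported."""
    donors = sorted(all_representatives)
    parent = {d: d for d in donors}

    def find(d):
        while parent[d] != d:
            parent[d] = parent[parent[d]]
            d = parent[d]
        return d

    thr = cfg.decision_threshold
    for i, da in enumerate(donors):
        for db in donors[i + 1:]:
            linked = False
            for ida, fpa in all_representatives[da].items():
                for idb, fpb in all_representatives[db].items():
                    if _cache is not None:
                        lod = _cache.lod(ida, idb)
                    else:
                        lod = total_lod(fpa, fpb, hmap, cfg).lod
                    if lod >= thr:
                        linked = True
                        break
                if linked:
                    break
            if linked:
                parent[find(da)] = find(db)
    groups: dict[str, list[str]] = {}
    for d in donors:
        groups.setdefault(find(d), []).append(d)
    return sorted([sorted(g) for g in groups.values() if len(g) > 1])


def contamination_profile(
    reads_a,
    reads_b,
    reference_fp: Fingerprint,
    hmap: HaplotypeMap,
    fractions: Sequence[float],
    total_reads: int,
    seed=0,
    filters: ReadFilterConfig = ReadFilterConfig(),
) -> list[tuple[float, float]]:
    """LOD against a reference as a function of contamination fraction.

    For each fraction q, a mixture of round(q * total_reads) reads from
    the contaminant ``reads_b`` and the remainder from ``reads_a`` is
    fingerprinted and compared to ``reference_fp``. ``reads_a``/``reads_b``
    are lists of alignment records (e.g. from :func:`simdata.simulate_reads`)
    or SAM/BAM paths.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def load(source):
        if isinstance(source, (str, Path)):
            import pysam

            with pysam.AlignmentFile(str(source), check_sq=False) as af:
                return list(af)
        return list(source)

    pool_a = load(reads_a)
    pool_b = load(reads_b)
    results = []
    for q in fractions:
        n_b = round(q * total_reads)
        n_a = total_reads - n_b
        if n_a > len(pool_a) or n_b > len(pool_b):
            raise InsufficientReadsError(
                f"fraction {q}: need {n_a}+{n_b} reads, have "
                f"{len(pool_a)}+{len(pool_b)}"
            )
        take_a = rng.choice(len(pool_a), size=n_a, replace=False)
        take_b = rng.choice(len(pool_b), size=n_b, replace=False)
        mixture = [pool_a[i] for i in take_a] + [pool_b[i] for i in take_b]
        fp = build_fingerprint(mixture, hmap, filters, sample_id=f"mix{q:.2f}")
        cfg = ScoringConfig()
        results.append((float(q), total_lod(fp, reference_fp, hmap, cfg).lod))
    return results
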