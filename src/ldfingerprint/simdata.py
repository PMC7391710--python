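"""Synthetic panels, individuals, reads, and planted-truth cohorts.

Everything here is a pure function of its seed, so tests and acceptance
runs are reproducible without any external data. Block LD structure is
generated directly: each block's anchor allele is drawn per haplotype at
the block MAF and member columns copy the anchor except at switched
sites, which are redrawn at the block MAF (so member-anchor r^2 is
(1 - switch_rate)^2 regardless of MAF); distinct blocks are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .fingerprinting import Fingerprint
from .haplotype_map import (
    PHASE_MINUS,
    PHASE_PLUS,
    HaplotypeBlock,
    HaplotypeMap,
    SnpRecord,
)
from .map_builder import PanelSnp, PhasedPanel

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# population model / panel simulation


@dataclass(frozen=True)
class PopulationModel:
    """Parameters for a block-structured phased panel."""

    n_blocks: int = 100
    snps_per_block: int | tuple[int, int] = 3
    maf_range: tuple[float, float] = (0.1, 0.5)
    within_block_switch_rate: float = 0.0
    n_haplotypes: int = 200
    inter_block_spacing_bp: int = 100_000
    intra_block_spacing_bp: int = 200
    chrom: str = "1"
    population_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.within_block_switch_rate < 0.5:
            raise ConfigurationError("within_block_switch_rate must be in [0, 0.5)")
        if self.n_blocks <= 0 or self.n_haplotypes <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_haplotypes % 2:
            raise ConfigurationError("n_haplotypes must be even")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")


def _block_sizes(model: PopulationModel, rng) -> np.ndarray:
    if isinstance(model.snps_per_block, int):
        return np.full(model.n_blocks, model.snps_per_block)
    lo, hi = model.snps_per_block
    return rng.integers(lo, hi + 1, size=model.n_blocks)


def simulate_panel(model: PopulationModel) -> PhasedPanel:
    """Draw a phased panel with the model's block LD structure.

    The returned panel carries a ``block_assignments`` attribute (list of
    per-block column-index lists, anchor first) used by :func:`truth_map`.
    Columns whose empirical alternate frequency exceeds 0.5 are flipped so
    that indicator 1 always marks the minor allele; this is what produces
    "-"-phased members for blocks with MAF near 0.5.
    """
    rng = _rng(model.seed)
    sizes = _block_sizes(model, rng)
    snps: list[PanelSnp] = []
    columns: list[np.ndarray] = []
    assignments: list[list[int]] = []
    H = model.n_haplotypes
    col_idx = 0
    for b, size in enumerate(sizes):
        maf = rng.uniform(*model.maf_range)
        base_pos = 1 + b * model.inter_block_spacing_bp
        anchor_col = (rng.random(H) < maf).astype(np.int8)
        block_cols: list[int] = []
        for k in range(int(size)):
            if k == 0:
                col = anchor_col
            else:
                # switched sites redraw at the block MAF instead of copying
                # the anchor, giving member-anchor r^2 = (1 - rate)^2
                # independent of MAF
                switches = rng.random(H) < model.within_block_switch_rate
                fresh = (rng.random(H) < maf).astype(np.int8)
                col = np.where(switches, fresh, anchor_col).astype(np.int8)
            major, minor = rng.choice(_BASES, size=2, replace=False)
            f = col.mean()
            if f > 0.5:  # keep indicator 1 = minor allele
                col = (1 - col).astype(np.int8)
                major, minor = minor, major
            pos = base_pos + k * model.intra_block_spacing_bp
            snps.append(PanelSnp(model.chrom, pos, f"b{b:05d}s{k:02d}", str(major), str(minor)))
            columns.append(col)
            block_cols.append(col_idx)
            col_idx += 1
        assignments.append(block_cols)
    populations = None
    if model.population_labels:
        labels = list(model.population_labels)
        populations = [labels[i % len(labels)] for i in range(H // 2)]
    panel = PhasedPanel(snps, np.stack(columns, axis=1), populations)
    panel.block_assignments = assignments  # type: ignore[attr-defined]
    return panel


def truth_map(panel: PhasedPanel) -> HaplotypeMap:
    """Haplotype map from a simulated panel's known block structure.

    Anchor = first SNP of each block; member phase from the sign of the
    allelic covariance with the anchor; per-member MAF stored, anchor MAF
    used for the block.
    """
    assignments = getattr(panel, "block_assignments", None)
    if assignments is None:
        raise ConfigurationError("panel was not produced by simulate_panel")
    blocks = []
    H = panel.haplotypes
    freqs = H.mean(axis=0)
    for cols in assignments:
        ai = cols[0]
        a = panel.snps[ai]
        anchor = SnpRecord(a.chrom, a.pos, a.name, a.major_allele, a.minor_allele,
                           min(float(freqs[ai]), 1 - float(freqs[ai])), a.name, PHASE_PLUS)
        members = [anchor]
        a_col = H[:, ai].astype(float)
        for mi in cols[1:]:
            m = panel.snps[mi]
            cov = float(np.cov(a_col, H[:, mi].astype(float))[0, 1])
            members.append(
                SnpRecord(m.chrom, m.pos, m.name, m.major_allele, m.minor_allele,
                          min(float(freqs[mi]), 1 - float(freqs[mi])), a.name,
                          PHASE_PLUS if cov >= 0 else PHASE_MINUS)
            )
        blocks.append(HaplotypeBlock(anchor, tuple(members)))
    return HaplotypeMap(blocks)


def random_map(
    n_blocks: int,
    snps_per_block: int = 1,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed=0,
    chrom: str = "1",
    inter_block_spacing_bp: int = 100_000,
    intra_block_spacing_bp: int = 200,
    minus_phase_rate: float = 0.0,
) -> HaplotypeMap:
    """A haplotype map drawn directly (no panel); members share the anchor
    MAF and are '+'-phased unless ``minus_phase_rate`` applies."""
    rng = _rng(seed)
    blocks = []
    for b in range(n_blocks):
        maf = float(rng.uniform(*maf_range))
        base_pos = 1 + b * inter_block_spacing_bp
        major, minor = rng.choice(_BASES, size=2, replace=False)
        name = f"blk{b:05d}a"
        anchor = SnpRecord(chrom, base_pos, name, str(major), str(minor), maf, name)
        members = [anchor]
        for k in range(1, snps_per_block):
            mmaj, mmin = rng.choice(_BASES, size=2, replace=False)
            phase = PHASE_MINUS if rng.random() < minus_phase_rate else PHASE_PLUS
            members.append(
                SnpRecord(chrom, base_pos + k * intra_block_spacing_bp,
                          f"blk{b:05d}m{k}", str(mmaj), str(mmin), maf, name, phase)
            )
        blocks.append(HaplotypeBlock(anchor, tuple(members)))
    return HaplotypeMap(blocks)


def singleton_map_from(hmap: HaplotypeMap) -> HaplotypeMap:
    """Break every SNP of a map out into its own single-SNP block.

    Each SNP keeps the block MAF of its original anchor (the map's working
    assumption), giving an equally sized panel of unlinked SNPs for
    LD-advantage comparisons.
    """
    blocks = []
    for block in hmap.blocks:
        for snp in block:
            rec = SnpRecord(snp.chrom, snp.pos, snp.name, snp.major_allele,
                            snp.minor_allele, block.block_maf, snp.name, PHASE_PLUS)
            blocks.append(HaplotypeBlock(rec, (rec,)))
    return HaplotypeMap(blocks)


# ---------------------------------------------------------------------------
# individuals


@dataclass(frozen=True)
class RelationshipSpec:
    kind: str = "unrelated"  # unrelated | parent_child | siblings | duplicate_donor

    def __post_init__(self):
        if self.kind not in ("unrelated", "parent_child", "siblings", "duplicate_donor"):
            raise ConfigurationError(f"unknown relationship kind {self.kind!r}")


@dataclass(frozen=True)
class Individual:
    """Diploid anchor-allele indicators per block: shape (2, n_blocks)."""

    haplotypes: np.ndarray  # int8, values 0 (major) / 1 (minor)

    @property
    def genotype(self) -> np.ndarray:
        """Minor-allele dosage per block (0, 1, or 2)."""
        return self.haplotypes.sum(axis=0)

    @property
    def n_blocks(self) -> int:
        return self.haplotypes.shape[1]


def _block_mafs(source) -> np.ndarray:
    if isinstance(source, HaplotypeMap):
        return np.array([b.block_maf for b in source.blocks])
    return np.asarray(source, dtype=float)


def sample_individual(
    source,
    relationship: RelationshipSpec = RelationshipSpec(),
    parents: Sequence[Individual] | None = None,
    seed=0,
) -> Individual:
    """Draw a diploid individual over a map's blocks.

    unrelated: both haplotypes population draws. parent_child: one
    haplotype transmitted per block from ``parents[0]`` (no recombination
    within blocks), the other a population draw. siblings: one haplotype
    from each of ``parents`` (two calls with the same parents yield
    siblings). duplicate_donor: an exact genotype copy of ``parents[0]``.
    """
    rng = _rng(seed)
    mafs = _block_mafs(source)
    n = len(mafs)
    kind = relationship.kind
    if kind == "unrelated":
        hap = (rng.random((2, n)) < mafs).astype(np.int8)
        return Individual(hap)
    if parents is None or not parents:
        raise ConfigurationError(f"relationship {kind} requires parents")
    if kind == "duplicate_donor":
        return Individual(parents[0].haplotypes.copy())
    if kind == "parent_child":
        parent = parents[0]
        pick = rng.integers(0, 2, size=n)
        transmitted = parent.haplotypes[pick, np.arange(n)]
        other = (rng.random(n) < mafs).astype(np.int8)
        return Individual(np.stack([transmitted, other]).astype(np.int8))
    if kind == "siblings":
        if len(parents) < 2:
            raise ConfigurationError("siblings require two parents")
        h = []
        for parent in parents[:2]:
            pick = rng.integers(0, 2, size=n)
            h.append(parent.haplotypes[pick, np.arange(n)])
        return Individual(np.stack(h).astype(np.int8))
    raise ConfigurationError(f"unknown relationship kind {kind!r}")


def related_pair(
    hmap: HaplotypeMap, kind: str, seed=0
) -> tuple[Individual, Individual]:
    """Convenience: a pair of individuals with the requested relationship."""
    rng = _rng(seed)
    if kind == "unrelated":
        return (sample_individual(hmap, seed=rng), sample_individual(hmap, seed=rng))
    if kind == "duplicate_donor":
        a = sample_individual(hmap, seed=rng)
        b = sample_individual(hmap, RelationshipSpec("duplicate_donor"), [a], rng)
        return a, b
    if kind == "parent_child":
        parent = sample_individual(hmap, seed=rng)
        child = sample_individual(hmap, RelationshipSpec("parent_child"), [parent], rng)
        return parent, child
    if kind == "siblings":
        p1 = sample_individual(hmap, seed=rng)
        p2 = sample_individual(hmap, seed=rng)
        s1 = sample_individual(hmap, RelationshipSpec("siblings"), [p1, p2], rng)
        s2 = sample_individual(hmap, RelationshipSpec("siblings"), [p1, p2], rng)
        return s1, s2
    raise ConfigurationError(f"unknown relationship kind {kind!r}")


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class AssayModel:
    """Read-emission parameters for one simulated assay."""

    covered_blocks: float | frozenset = 1.0  # fraction, or explicit anchor names
    #: which member indices within each block reads may cover:
    #: "all" | "even" | "odd" | explicit tuple of indices (0 = anchor)
    member_subset: str | tuple[int, ...] = "all"
    depth_lambda: float = 5.0
    base_error_rate: float = 0.001
    read_length: int = 50
    mapping_quality: int = 60
    base_quality: int = 30
    duplicate_fraction: float = 0.0
    secondary_fraction: float = 0.0

    def __post_init__(self):
        if self.depth_lambda < 0:
            raise ConfigurationError("depth_lambda must be >= 0")
        if not 0.0 < self.base_error_rate <= 0.5:
            raise ConfigurationError("base_error_rate must be in (0, 0.5]")


def _member_genotype(snp, anchor_dosage_haps: np.ndarray) -> np.ndarray:
    """Member-allele indicators on both haplotypes, given anchor indicators."""
    if snp.phase == PHASE_PLUS:
        return anchor_dosage_haps
    return 1 - anchor_dosage_haps


def _covered_sites(hmap: HaplotypeMap, assay: AssayModel, rng):
    """Yield (block_index, snp) for sites this assay may cover."""
    if isinstance(assay.covered_blocks, float):
        block_on = rng.random(len(hmap.blocks)) < assay.covered_blocks
    else:
        names = set(assay.covered_blocks)
        block_on = np.array([b.anchor.name in names for b in hmap.blocks])
    for bi, block in enumerate(hmap.blocks):
        if not block_on[bi]:
            continue
        rule = assay.member_subset
        for k, snp in enumerate(block):
            if isinstance(rule, tuple):
                if k not in rule:
                    continue
            elif rule == "even" and k % 2 != 0:
                continue
            elif rule == "odd" and k % 2 != 1:
                continue
            yield bi, snp


def alignment_header(hmap: HaplotypeMap):
    """pysam header covering the map's contigs with generous lengths."""
    import pysam

    contigs: dict[str, int] = {}
    for snp in hmap.snps():
        contigs[snp.chrom] = max(contigs.get(snp.chrom, 0), snp.pos)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": l + 1_000_000} for c, l in contigs.items()],
        }
    )


def simulate_reads(
    individual: Individual,
    hmap: HaplotypeMap,
    assay: AssayModel = AssayModel(),
    seed=0,
):
    """Emit single-end SAM records over the assay's footprint.

    Per covered site, Poisson(depth_lambda) reads; each read samples one of
    the individual's two alleles uniformly and flips it with probability
    ``base_error_rate``. A configurable fraction of reads is flagged
    duplicate or secondary to exercise the filters. Returns
    ``(header, [AlignedSegment, ...])``.
    """
    import pysam

    rng = _rng(seed)
    header = alignment_header(hmap)
    records = []
    counter = 0
    other = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for bi, snp in _covered_sites(hmap, assay, rng):
        anchor_haps = individual.haplotypes[:, bi]
        site_haps = _member_genotype(snp, anchor_haps)
        depth = rng.poisson(assay.depth_lambda)
        for _ in range(depth):
            hap = int(rng.integers(0, 2))
            indicator = int(site_haps[hap])
            base = snp.minor_allele if indicator else snp.major_allele
            if rng.random() < assay.base_error_rate:
                base = snp.minor_allele if base == snp.major_allele else snp.major_allele
            offset = int(rng.integers(0, assay.read_length))
            start0 = snp.pos - 1 - offset
            if start0 < 0:
                offset += start0
                start0 = 0
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"sim{counter:09d}"
            counter += 1
            seq = ["A"] * assay.read_length
            seq[offset] = base
            seg.query_sequence = "".join(seq)
            seg.reference_name = snp.chrom
            seg.reference_start = start0
            seg.cigarstring = f"{assay.read_length}M"
            seg.mapping_quality = assay.mapping_quality
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(assay.base_quality + 33) * assay.read_length
            )
            flag = 0
            if rng.random() < assay.duplicate_fraction:
                flag |= 0x400
            if rng.random() < assay.secondary_fraction:
                flag |= 0x100
            seg.flag = flag
            records.append(seg)
    return header, records


def write_sam(header, records, path) -> None:
    import pysam

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


# ---------------------------------------------------------------------------
# fast fingerprint-level simulation


def simulate_fingerprint(
    individual: Individual,
    hmap: HaplotypeMap,
    depth_lambda: float = 30.0,
    base_error_rate: float = 0.01,
    seed=0,
    sample_id: str = "SAMPLE",
    covered_fraction: float = 1.0,
) -> Fingerprint:
    """Draw a fingerprint directly at the observation level.

    Equivalent in distribution to simulating reads at one site per block
    and extracting: per block, Poisson(depth_lambda) observations, each the
    minor allele with probability e, 0.5, or 1-e by genotype.
    """
    rng = _rng(seed)
    e = base_error_rate
    n = len(hmap.blocks)
    geno = individual.genotype
    n_obs = rng.poisson(depth_lambda, size=n)
    if covered_fraction < 1.0:
        n_obs = np.where(rng.random(n) < covered_fraction, n_obs, 0)
    p_minor = np.choose(geno, [e, 0.5, 1.0 - e])
    k_min = rng.binomial(n_obs, p_minor)
    k_maj = n_obs - k_min
    ll = np.stack(
        [
            k_maj * math.log10(1 - e) + k_min * math.log10(e),
            n_obs * math.log10(0.5),
            k_maj * math.log10(e) + k_min * math.log10(1 - e),
        ],
        axis=1,
    )
    ll[n_obs == 0] = 0.0
    return Fingerprint(sample_id, hmap.checksum, hmap.anchor_names, ll, n_obs)


def simulate_site_counts(
    individual: Individual,
    hmap: HaplotypeMap,
    assay: AssayModel = AssayModel(),
    seed=0,
) -> dict[str, tuple[int, int]]:
    """Per-site (n_major, n_minor) observation counts in *site* allele space.

    One site-level draw that can be fingerprinted against different maps
    covering the same SNPs (e.g. block map vs singleton map) for
    like-for-like comparisons at an identical read budget.
    """
    rng = _rng(seed)
    counts: dict[str, tuple[int, int]] = {}
    e = assay.base_error_rate
    for bi, snp in _covered_sites(hmap, assay, rng):
        site_haps = _member_genotype(snp, individual.haplotypes[:, bi])
        g = int(site_haps.sum())
        depth = int(rng.poisson(assay.depth_lambda))
        p_minor = (e, 0.5, 1.0 - e)[g]
        k_min = int(rng.binomial(depth, p_minor))
        counts[snp.name] = (depth - k_min, k_min)
    return counts


def fingerprint_from_site_counts(
    counts: Mapping[str, tuple[int, int]],
    hmap: HaplotypeMap,
    base_error_rate: float,
    sample_id: str = "SAMPLE",
) -> Fingerprint:
    """Aggregate site-level counts into a fingerprint under ``hmap``.

    Site alleles are translated to anchor alleles via each SNP's phase;
    sites absent from the map are ignored.
    """
    e = base_error_rate
    by_name = {snp.name: (block, snp) for block in hmap.blocks for snp in block}
    n = len(hmap.blocks)
    anchor_pos = {b.anchor.name: i for i, b in enumerate(hmap.blocks)}
    k_maj = np.zeros(n, dtype=np.int64)
    k_min = np.zeros(n, dtype=np.int64)
    for name, (n_site_major, n_site_minor) in counts.items():
        hit = by_name.get(name)
        if hit is None:
            continue
        block, snp = hit
        i = anchor_pos[block.anchor.name]
        if snp.phase == PHASE_PLUS:
            k_maj[i] += n_site_major
            k_min[i] += n_site_minor
        else:
            k_maj[i] += n_site_minor
            k_min[i] += n_site_major
    n_obs = k_maj + k_min
    ll = np.stack(
        [
            k_maj * math.log10(1 - e) + k_min * math.log10(e),
            n_obs * math.log10(0.5),
            k_maj * math.log10(e) + k_min * math.log10(1 - e),
        ],
        axis=1,
    )
    ll[n_obs == 0] = 0.0
    return Fingerprint(sample_id, hmap.checksum, hmap.anchor_names, ll, n_obs)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """A planted-truth cohort: map, manifest rows, fingerprints, truth."""

    hmap: HaplotypeMap
    entries: list  # of screening.ManifestEntry
    fingerprints: dict[str, Fingerprint]
    truth: dict[str, str]  # dataset_id -> true donor
    individuals: dict[str, Individual]  # true donor -> genotype


def make_cohort(
    n_donors: int,
    datasets_per_donor: int,
    n_blocks: int = 1000,
    depth_lambda: float = 30.0,
    base_error_rate: float = 0.01,
    n_swaps: int = 0,
    swap_spec: Sequence[tuple[str, str]] | None = None,
    duplicate_donor_spec: Mapping | None = None,
    hmap: HaplotypeMap | None = None,
    seed=0,
) -> Cohort:
    """Simulate a screening cohort with planted swaps.

    ``swap_spec`` gives explicit (dataset_id, true_donor) overrides;
    ``n_swaps`` plants that many random swaps instead. A
    ``duplicate_donor_spec`` of the form ``{"nominal": [d1, d2], "n_true": k}``
    makes the listed nominal donors draw their datasets round-robin from
    ``k`` distinct true individuals (modelling repeated accessioning of
    commercial lines).
    """
    from .screening import ManifestEntry

    rng = _rng(seed)
    if hmap is None:
        hmap = random_map(n_blocks, snps_per_block=1, seed=rng.integers(2**31))
    donors = [f"D{d:03d}" for d in range(n_donors)]
    individuals: dict[str, Individual] = {
        d: sample_individual(hmap, seed=rng) for d in donors
    }
    dup_nominal: dict[str, list[str]] = {}
    if duplicate_donor_spec:
        nominal = list(duplicate_donor_spec["nominal"])
        n_true = int(duplicate_donor_spec["n_true"])
        true_ids = [f"{nominal[0]}_true{i}" for i in range(n_true)]
        for tid in true_ids:
            individuals[tid] = sample_individual(hmap, seed=rng)
        counter = 0
        for d in nominal:
            if d not in donors:
                raise ConfigurationError(f"duplicate donor {d} not in cohort")
            assigned = []
            for _ in range(datasets_per_donor):
                assigned.append(true_ids[counter % n_true])
                counter += 1
            dup_nominal[d] = assigned

    truth: dict[str, str] = {}
    entries: list[ManifestEntry] = []
    for d in donors:
        for k in range(datasets_per_donor):
            ds = f"{d}_ds{k:02d}"
            if d in dup_nominal:
                truth[ds] = dup_nominal[d][k]
            else:
                truth[ds] = d
            entries.append(ManifestEntry(ds, d, ""))

    if swap_spec:
        for ds, true_donor in swap_spec:
            if true_donor not in individuals:
                individuals[true_donor] = sample_individual(hmap, seed=rng)
            truth[ds] = true_donor
    elif n_swaps:
        swappable = [e.dataset_id for e in entries if e.donor not in dup_nominal]
        chosen = rng.choice(len(swappable), size=n_swaps, replace=False)
        for i in chosen:
            ds = swappable[i]
            nominal = ds.split("_ds")[0]
            others = [d for d in donors if d != nominal and d not in dup_nominal]
            truth[ds] = others[int(rng.integers(len(others)))]

    fingerprints = {
        e.dataset_id: simulate_fingerprint(
            individuals[truth[e.dataset_id]], hmap, depth_lambda, base_error_rate,
            seed=rng, sample_id=e.dataset_id,
        )
        for e in entries
    }
    return Cohort(hmap, entries, fingerprints, truth, individuals)
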