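"""From aligned reads to per-block genotype likelihoods (fingerprints).

Base observations at any SNP of a block are translated to the block
anchor's major/minor alleles via the stored phase, then folded into
log10 likelihoods for the three diploid genotypes AA / AB / BB. One
read-pair contributes at most one observation map-wide, preserving the
independence assumption of the scoring model.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._util import atomic_write, phred_to_error
from .errors import (
    ChecksumMismatchError,
    ContigMismatchError,
    DuplicateSourceError,
    LdFingerprintError,
)
from .haplotype_map import PHASE_PLUS, HaplotypeMap

logger = logging.getLogger(__name__)

#: error probabilities are clamped to this range: 0 would give -inf logs,
#: 0.5 is the information-free bound.
ERROR_PROB_MIN = 1e-6
ERROR_PROB_MAX = 0.5

GENOTYPES = ("AA", "AB", "BB")


class Allele(enum.Enum):
    """An observed base expressed in the *anchor's* allele space."""

    MAJOR = 0
    MINOR = 1


@dataclass(frozen=True)
class ReadFilterConfig:
    """Read/base acceptance rules.

    ``min_mapping_quality`` is an exclusive bound (MQ must be strictly
    greater); ``min_base_quality`` is inclusive.
    """

    min_mapping_quality: int = 20
    min_base_quality: int = 20
    exclude_secondary: bool = True
    exclude_duplicates: bool = True

    def __post_init__(self):
        if self.min_mapping_quality < 0 or self.min_base_quality < 0:
            raise LdFingerprintError("quality thresholds must be >= 0")


@dataclass(frozen=True)
class AlleleObservation:
    """A single filtered base observation, already anchor-translated."""

    block_id: str
    allele: Allele
    error_prob: float
    source_id: str

    def __post_init__(self):
        if not ERROR_PROB_MIN <= self.error_prob <= ERROR_PROB_MAX:
            raise LdFingerprintError(
                f"error_prob {self.error_prob} outside "
                f"[{ERROR_PROB_MIN}, {ERROR_PROB_MAX}]"
            )


@dataclass(frozen=True)
class BlockLikelihoods:
    """log10 genotype likelihoods for one block plus observation count."""

    ll_aa: float = 0.0
    ll_ab: float = 0.0
    ll_bb: float = 0.0
    n_observations: int = 0

    def __post_init__(self):
        if self.n_observations == 0 and (self.ll_aa or self.ll_ab or self.ll_bb):
            raise LdFingerprintError("zero-observation block must have zero likelihoods")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.ll_aa, self.ll_ab, self.ll_bb])

    def argmax_genotype(self) -> str:
        return GENOTYPES[int(np.argmax(self.array))]


def observation_likelihood(allele: Allele, error_prob: float, genotype: str) -> float:
    """P(observed allele, error prob | diploid genotype).

    AA: 1-e for MAJOR, e for MINOR; AB: 0.5 regardless; BB mirrors AA.
    """
    e = error_prob
    if genotype == "AA":
        return 1.0 - e if allele is Allele.MAJOR else e
    if genotype == "AB":
        return 0.5
    if genotype == "BB":
        return e if allele is Allele.MAJOR else 1.0 - e
    raise ValueError(f"unknown genotype {genotype!r}")


def block_likelihoods(observations: Sequence[AlleleObservation]) -> BlockLikelihoods:
    """Fold independent observations of one block into log10 likelihoods."""
    if not observations:
        return BlockLikelihoods()
    block_ids = {o.block_id for o in observations}
    if len(block_ids) != 1:
        raise LdFingerprintError(f"observations span multiple blocks: {sorted(block_ids)}")
    sources = [o.source_id for o in observations]
    if len(set(sources)) != len(sources):
        raise DuplicateSourceError(
            f"duplicate read-pair evidence in block {observations[0].block_id}"
        )
    ll = np.zeros(3)
    for obs in observations:
        ll += np.log10(
            [observation_likelihood(obs.allele, obs.error_prob, g) for g in GENOTYPES]
        )
    return BlockLikelihoods(float(ll[0]), float(ll[1]), float(ll[2]), len(observations))


class Fingerprint:
    """Per-block log10 genotype likelihoods for one dataset.

    Internally stored as arrays aligned with the map's block order;
    ``map_checksum`` binds the fingerprint to its haplotype map.
    """

    def __init__(
        self,
        sample_id: str,
        map_checksum: str,
        anchor_names: Sequence[str],
        ll: np.ndarray,
        n_obs: np.ndarray,
    ):
        ll = np.asarray(ll, dtype=float)
        n_obs = np.asarray(n_obs, dtype=np.int64)
        if ll.shape != (len(anchor_names), 3) or n_obs.shape != (len(anchor_names),):
            raise LdFingerprintError("fingerprint array shapes do not match block count")
        self.sample_id = sample_id
        self.map_checksum = map_checksum
        self.anchor_names = tuple(anchor_names)
        self.ll = ll
        self.n_obs = n_obs
        self._anchor_index = {a: i for i, a in enumerate(self.anchor_names)}

    @classmethod
    def from_block_likelihoods(
        cls,
        sample_id: str,
        hmap: HaplotypeMap,
        per_block: Mapping[str, BlockLikelihoods],
    ) -> "Fingerprint":
        names = hmap.anchor_names
        unknown = set(per_block) - set(names)
        if unknown:
            raise LdFingerprintError(f"blocks not in map: {sorted(unknown)}")
        ll = np.zeros((len(names), 3))
        n_obs = np.zeros(len(names), dtype=np.int64)
        for i, name in enumerate(names):
            bl = per_block.get(name)
            if bl is not None:
                ll[i] = bl.array
                n_obs[i] = bl.n_observations
        return cls(sample_id, hmap.checksum, names, ll, n_obs)

    def block(self, anchor_name: str) -> BlockLikelihoods:
        i = self._anchor_index[anchor_name]
        return BlockLikelihoods(*self.ll[i], int(self.n_obs[i]))

    @property
    def n_covered_blocks(self) -> int:
        return int((self.n_obs > 0).sum())

    def __repr__(self) -> str:
        return (f"Fingerprint({self.sample_id!r}, {len(self.anchor_names)} blocks, "
                f"{self.n_covered_blocks} covered)")


# ---------------------------------------------------------------------------
# observation extraction from alignments


def _site_index(hmap: HaplotypeMap) -> dict[str, dict[int, tuple]]:
    """contig -> {0-based pos -> (anchor_name, snp)}."""
    index: dict[str, dict[int, tuple]] = {}
    for block in hmap.blocks:
        for snp in block:
            index.setdefault(snp.chrom, {})[snp.pos - 1] = (block.anchor.name, snp)
    return index


def _clamp_error(e: float) -> float:
    return min(max(e, ERROR_PROB_MIN), ERROR_PROB_MAX)


def _open_alignments(alignments):
    """Accept a path, an open AlignmentFile, or an iterable of records."""
    import pysam

    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        return af.header, af, True
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments.header, alignments, False
    records = list(alignments)
    header = records[0].header if records else None
    return header, records, False


def extract_observations(
    alignments,
    hmap: HaplotypeMap,
    filters: ReadFilterConfig = ReadFilterConfig(),
) -> list[AlleleObservation]:
    """Scan alignments for usable bases over map SNPs.

    Per retained read-pair at most one observation is emitted (the first
    usable site in (chrom, pos) order). Bases from overlapping mates at
    the same site are merged: agreeing bases keep the higher quality,
    disagreeing bases void the site for that pair.
    """
    header, records, close = _open_alignments(alignments)
    sites = _site_index(hmap)
    if header is not None and len(header.references or ()) > 0:
        have = set(header.references)
        missing = [c for c in sites if c not in have]
        if missing:
            raise ContigMismatchError(missing)

    # qname -> {(chrom, pos): (allele, error_prob, base, bq)}
    candidates: dict[str, dict[tuple, tuple]] = {}
    n_records = 0
    try:
        for read in records:
            n_records += 1
            if read.is_unmapped:
                continue
            if filters.exclude_secondary and (read.is_secondary or read.is_supplementary):
                continue
            if filters.exclude_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality <= filters.min_mapping_quality:
                continue
            contig_sites = sites.get(read.reference_name)
            if not contig_sites:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                hit = contig_sites.get(rpos)
                if hit is None:
                    continue
                anchor_name, snp = hit
                bq = quals[qpos]
                if bq < filters.min_base_quality:
                    continue
                base = seq[qpos].upper()
                if base == snp.major_allele:
                    site_allele = Allele.MAJOR
                elif base == snp.minor_allele:
                    site_allele = Allele.MINOR
                else:
                    continue  # N or third allele
                # translate to the anchor's allele space via phase
                if snp.phase == PHASE_PLUS:
                    allele = site_allele
                else:
                    allele = Allele.MINOR if site_allele is Allele.MAJOR else Allele.MAJOR
                e = _clamp_error(phred_to_error(bq))
                key = (snp.chrom, snp.pos)
                pair_sites = candidates.setdefault(read.query_name, {})
                if key not in pair_sites:
                    pair_sites[key] = (allele, e, base, bq, anchor_name)
                else:
                    prev = pair_sites[key]
                    if prev is None:
                        continue  # site already voided by mate disagreement
                    if prev[2] != base:
                        pair_sites[key] = None  # disagreement: void the site
                    elif bq > prev[3]:
                        pair_sites[key] = (allele, e, base, bq, anchor_name)
    finally:
        if close:
            records.close()

    observations: list[AlleleObservation] = []
    for qname, pair_sites in candidates.items():
        usable = sorted(
            (key, val) for key, val in pair_sites.items() if val is not None
        )
        if not usable:
            continue
        (_, _), (allele, e, _, _, anchor_name) = usable[0]
        observations.append(AlleleObservation(anchor_name, allele, e, qname))
    logger.debug("extract_observations: %d observations from %d records",
                 len(observations), n_records)
    return observations


def build_fingerprint(
    alignments,
    hmap: HaplotypeMap,
    filters: ReadFilterConfig = ReadFilterConfig(),
    sample_id: str = "SAMPLE",
) -> Fingerprint:
    """Extract observations and fold them into a per-block fingerprint.

    Blocks with no observations are retained with (0, 0, 0) likelihoods so
    they contribute exactly zero to any LOD comparison.
    """
    observations = extract_observations(alignments, hmap, filters)
    grouped: dict[str, list[AlleleObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.block_id, []).append(obs)
    per_block = {name: block_likelihoods(obs) for name, obs in grouped.items()}
    return Fingerprint.from_block_likelihoods(sample_id, hmap, per_block)


# ---------------------------------------------------------------------------
# VCF persistence
#
# The fingerprint VCF stores full-precision log10 likelihoods in a GL-style
# FORMAT field. We read/write the records as text rather than through
# htslib, whose float32 FORMAT storage cannot honour the 1e-6 round-trip
# contract for deep fingerprints; the output is nonetheless valid VCF 4.2.

_GT_CODES = {"AA": "0/0", "AB": "0/1", "BB": "1/1"}


def fingerprint_to_vcf(fp: Fingerprint, hmap: HaplotypeMap, path) -> None:
    """Write one VCF record per anchor with GT (argmax) and GL fields."""
    if fp.map_checksum != hmap.checksum:
        raise ChecksumMismatchError(
            "fingerprint is bound to a different haplotype map"
        )
    contigs: dict[str, int] = {}
    for snp in hmap.snps():
        contigs[snp.chrom] = max(contigs.get(snp.chrom, 0), snp.pos)
    with atomic_write(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldfingerprint\n")
        fh.write(f"##ldfp_map_checksum={fp.map_checksum}\n")
        for chrom, maxpos in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1_000_000}>\n")
        fh.write('##INFO=<ID=NOBS,Number=1,Type=Integer,'
                 'Description="Read-pair observations at this block">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GL,Number=G,Type=Float,'
                 'Description="log10 genotype likelihoods (AA,AB,BB)">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{fp.sample_id}\n")
        for block in hmap.blocks:
            anchor = block.anchor
            bl = fp.block(anchor.name)
            gt = _GT_CODES[bl.argmax_genotype()] if bl.n_observations else "./."
            gl = ",".join(f"{v:.10g}" for v in bl.array)
            fh.write(
                f"{anchor.chrom}\t{anchor.pos}\t{anchor.name}\t{anchor.major_allele}\t"
                f"{anchor.minor_allele}\t.\t.\tNOBS={bl.n_observations}\t"
                f"GT:GL\t{gt}:{gl}\n"
            )


def vcf_to_fingerprint(path, hmap: HaplotypeMap) -> Fingerprint:
    """Load a fingerprint VCF written by :func:`fingerprint_to_vcf`.

    Anchors absent from the file become no-observation blocks; records not
    matching any map anchor are counted and logged, not errors.
    """
    per_block: dict[str, BlockLikelihoods] = {}
    checksum = None
    sample_id = "SAMPLE"
    n_extra = 0
    anchor_keys = {b.anchor.key: b.anchor.name for b in hmap.blocks}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if line.startswith("##ldfp_map_checksum="):
                    checksum = line.split("=", 1)[1]
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    sample_id = cols[9]
                continue
            if not line:
                continue
            fields = line.split("\t")
            chrom, pos = fields[0], int(fields[1])
            anchor_name = anchor_keys.get((chrom, pos))
            if anchor_name is None:
                n_extra += 1
                continue
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            n_obs = int(info.get("NOBS", "0"))
            fmt_keys = fields[8].split(":")
            fmt_vals = fields[9].split(":")
            sample = dict(zip(fmt_keys, fmt_vals))
            gl = [float(v) for v in sample["GL"].split(",")]
            if n_obs == 0:
                per_block[anchor_name] = BlockLikelihoods()
            else:
                per_block[anchor_name] = BlockLikelihoods(*gl, n_obs)
    if n_extra:
        logger.info("vcf_to_fingerprint: ignored %d non-map records", n_extra)
    if checksum is not None and checksum != hmap.checksum:
        raise ChecksumMismatchError(
            f"fingerprint VCF {path} was extracted against a different map"
        )
    fp = Fingerprint.from_block_likelihoods(sample_id, hmap, per_block)
    return fp
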