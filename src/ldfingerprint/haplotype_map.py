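"""Haplotype maps: LD blocks of SNPs around independent anchor SNPs.

A haplotype map is the reference structure fingerprinting runs against: an
ordered collection of blocks, each an anchor SNP plus zero or more member
SNPs whose alleles are phase-mapped onto the anchor's major/minor alleles.
All SNPs in a block share the anchor's allele frequency for the purpose of
genotype priors.

File dialect (tab-delimited, UTF-8, ``#`` comments)::

    CHROM  POS  NAME  MAJOR  MINOR  MAF  ANCHOR  PHASE

One line per SNP; anchors carry ``ANCHOR == NAME`` and ``PHASE == +``;
member lines follow their anchor. MAF is printed with six decimals.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from .errors import MapFormatError, MapStructureError, MapValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
HEADER_COLUMNS = ("CHROM", "POS", "NAME", "MAJOR", "MINOR", "MAF", "ANCHOR", "PHASE")

#: phase flags: "+" means this SNP's major allele rides on haplotypes with the
#: anchor's major allele; "-" means it rides with the anchor's minor allele.
PHASE_PLUS = "+"
PHASE_MINUS = "-"


@dataclass(frozen=True)
class SnpRecord:
    """One bi-allelic SNP belonging to a haplotype block."""

    chrom: str
    pos: int
    name: str
    major_allele: str
    minor_allele: str
    maf: float
    anchor_name: str
    phase: str = PHASE_PLUS

    def __post_init__(self):
        if self.pos < 1:
            raise MapValidationError(f"{self.name}: position must be >= 1, got {self.pos}")
        if self.major_allele not in VALID_BASES or self.minor_allele not in VALID_BASES:
            raise MapValidationError(
                f"{self.name}: alleles must be single bases in ACGT "
                f"(got {self.major_allele!r}/{self.minor_allele!r})"
            )
        if self.major_allele == self.minor_allele:
            raise MapValidationError(f"{self.name}: major and minor alleles are identical")
        if not 0.0 <= self.maf <= 0.5:
            raise MapValidationError(f"{self.name}: MAF must be in [0, 0.5], got {self.maf}")
        if self.phase not in (PHASE_PLUS, PHASE_MINUS):
            raise MapValidationError(f"{self.name}: phase must be '+' or '-', got {self.phase!r}")
        if self.is_anchor and self.phase != PHASE_PLUS:
            raise MapValidationError(f"{self.name}: anchor SNPs must have phase '+'")

    @property
    def is_anchor(self) -> bool:
        return self.anchor_name == self.name

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class HaplotypeBlock:
    """An anchor SNP plus its phase-mapped members (anchor first)."""

    anchor: SnpRecord
    members: tuple[SnpRecord, ...]

    def __post_init__(self):
        if not self.anchor.is_anchor:
            raise MapStructureError(
                f"block anchor {self.anchor.name} does not reference itself "
                f"(anchor_name={self.anchor.anchor_name})"
            )
        object.__setattr__(
            self,
            "members",
            (self.anchor,) + tuple(
                sorted((m for m in self.members if m.name != self.anchor.name),
                       key=lambda s: s.key)
            ),
        )
        for member in self.members:
            if member.anchor_name != self.anchor.name:
                raise MapStructureError(
                    f"member {member.name} references anchor {member.anchor_name}, "
                    f"not {self.anchor.name}"
                )
        keys = [m.key for m in self.members]
        if len(set(keys)) != len(keys):
            raise MapStructureError(f"block {self.anchor.name} has duplicate positions")

    @property
    def block_maf(self) -> float:
        """Allele frequency used for the whole block (the anchor's)."""
        return self.anchor.maf

    @property
    def size(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.members)


class HaplotypeMap:
    """Ordered collection of haplotype blocks with a (chrom, pos) index."""

    def __init__(self, blocks: Iterable[HaplotypeBlock]):
        self.blocks: tuple[HaplotypeBlock, ...] = tuple(
            sorted(blocks, key=lambda b: b.anchor.key)
        )
        self.warnings: list[str] = []
        self._index: dict[tuple[str, int], tuple[HaplotypeBlock, SnpRecord]] = {}
        anchor_names: set[str] = set()
        for block in self.blocks:
            if block.anchor.name in anchor_names:
                raise MapStructureError(f"duplicate anchor {block.anchor.name}")
            anchor_names.add(block.anchor.name)
            for snp in block:
                if snp.key in self._index:
                    raise MapStructureError(
                        f"position {snp.chrom}:{snp.pos} appears in more than one block"
                    )
                self._index[snp.key] = (block, snp)
        self._by_anchor = {b.anchor.name: b for b in self.blocks}

    # -- lookups ---------------------------------------------------------

    def lookup(self, chrom: str, pos: int) -> tuple[HaplotypeBlock, SnpRecord] | None:
        return self._index.get((chrom, pos))

    def block_for_anchor(self, anchor_name: str) -> HaplotypeBlock:
        return self._by_anchor[anchor_name]

    @property
    def anchors(self) -> tuple[SnpRecord, ...]:
        return tuple(b.anchor for b in self.blocks)

    @property
    def anchor_names(self) -> tuple[str, ...]:
        return tuple(b.anchor.name for b in self.blocks)

    def snps(self) -> Iterator[SnpRecord]:
        for block in self.blocks:
            yield from block

    @property
    def n_snps(self) -> int:
        return len(self._index)

    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for block in self.blocks:
            for snp in block:
                seen.setdefault(snp.chrom, None)
        return list(seen)

    # -- identity --------------------------------------------------------

    @property
    def checksum(self) -> str:
        """SHA-256 of the canonical serialized form; binds fingerprints to maps."""
        buf = io.StringIO()
        _write_body(self, buf)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()

    def __eq__(self, other) -> bool:
        return isinstance(other, HaplotypeMap) and self.blocks == other.blocks

    def __len__(self) -> int:
        return len(self.blocks)

    def __repr__(self) -> str:
        return f"HaplotypeMap({len(self.blocks)} blocks, {self.n_snps} SNPs)"


# ---------------------------------------------------------------------------
# file I/O


def _format_maf(maf: float) -> str:
    """Shortest exact decimal representation, padded to >= 6 decimals."""
    s = repr(float(maf))
    if "e" in s or "E" in s:
        s = f"{maf:.20f}".rstrip("0")
    if "." not in s:
        s += "."
    int_part, frac = s.split(".")
    return f"{int_part}.{frac.ljust(6, '0')}"


def _write_body(hmap: HaplotypeMap, handle) -> None:
    handle.write("\t".join(HEADER_COLUMNS) + "\n")
    for block in hmap.blocks:
        for snp in block:
            handle.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.name}\t{snp.major_allele}\t"
                f"{snp.minor_allele}\t{_format_maf(snp.maf)}\t"
                f"{snp.anchor_name}\t{snp.phase}\n"
            )


def write_map(hmap: HaplotypeMap, path) -> None:
    """Serialize a map to the tab-delimited dialect (atomic replace)."""
    from ._util import atomic_write

    with atomic_write(path) as handle:
        handle.write("# ldfingerprint haplotype map\n")
        _write_body(hmap, handle)


def read_map(path) -> HaplotypeMap:
    """Parse a haplotype-map file; raises on malformed or inconsistent input."""
    rows: list[tuple[int, SnpRecord]] = []
    header_seen = False
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != HEADER_COLUMNS:
                    raise MapFormatError(
                        f"expected header {' '.join(HEADER_COLUMNS)}, got {line!r}", lineno
                    )
                header_seen = True
                continue
            if len(fields) != len(HEADER_COLUMNS):
                raise MapFormatError(
                    f"expected {len(HEADER_COLUMNS)} tab-separated fields, got {len(fields)}",
                    lineno,
                )
            chrom, pos_s, name, major, minor, maf_s, anchor, phase = fields
            try:
                pos = int(pos_s)
                maf = float(maf_s)
            except ValueError as exc:
                raise MapFormatError(str(exc), lineno) from exc
            try:
                rows.append((lineno, SnpRecord(chrom, pos, name, major, minor, maf, anchor, phase)))
            except MapValidationError as exc:
                raise MapFormatError(str(exc), lineno) from exc
    if not header_seen:
        raise MapFormatError("missing header line")
    return _assemble(rows)


def _assemble(rows: list[tuple[int, SnpRecord]]) -> HaplotypeMap:
    anchors = {snp.name: snp for _, snp in rows if snp.is_anchor}
    members: dict[str, list[SnpRecord]] = {name: [] for name in anchors}
    for _, snp in rows:
        if snp.is_anchor:
            continue
        if snp.anchor_name not in anchors:
            raise MapStructureError(
                f"SNP {snp.name} references unknown anchor {snp.anchor_name}"
            )
        members[snp.anchor_name].append(snp)
    blocks = [
        HaplotypeBlock(anchor, (anchor, *sorted(members[name], key=lambda s: s.key)))
        for name, anchor in anchors.items()
    ]
    return HaplotypeMap(blocks)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    """One validation finding; violations are data, not exceptions."""

    kind: str
    snp: str
    message: str
    value: float | None = None


def validate_map(
    hmap: HaplotypeMap,
    panel=None,
    min_maf: float = 0.10,
    anchor_r2_max: float = 0.10,
    member_r2_min: float = 0.85,
) -> list[Violation]:
    """Check MAF floors and, given a phased panel, the LD structure.

    With a panel: every member must have r^2 >= ``member_r2_min`` with its
    anchor, every anchor pair r^2 <= ``anchor_r2_max``, and each member's
    stored phase must match the sign of its allelic association with the
    anchor.
    """
    import numpy as np

    violations: list[Violation] = []
    for snp in hmap.snps():
        if snp.maf < min_maf:
            violations.append(
                Violation("maf_below_minimum", snp.name,
                          f"MAF {snp.maf:.4f} < {min_maf}", snp.maf)
            )
    if panel is None:
        return violations

    def col(name):
        return panel.column(name).astype(float)

    for block in hmap.blocks:
        anchor_col = col(block.anchor.name)
        for member in block.members[1:]:
            member_col = col(member.name)
            cov = float(np.cov(anchor_col, member_col)[0, 1])
            denom = anchor_col.std() * member_col.std()
            r2 = (np.corrcoef(anchor_col, member_col)[0, 1] ** 2) if denom > 0 else 0.0
            if r2 < member_r2_min:
                violations.append(
                    Violation("member_r2_below_minimum", member.name,
                              f"r^2 {r2:.4f} with anchor {block.anchor.name} "
                              f"< {member_r2_min}", r2)
                )
            expected_phase = PHASE_PLUS if cov >= 0 else PHASE_MINUS
            if member.phase != expected_phase:
                violations.append(
                    Violation("phase_mismatch", member.name,
                              f"stored phase {member.phase} but panel association "
                              f"sign implies {expected_phase}")
                )
    # anchor-pair independence, vectorized over the anchor columns
    anchor_names = hmap.anchor_names
    if len(anchor_names) > 1:
        mat = np.stack([col(name) for name in anchor_names])
        sd = mat.std(axis=1)
        ok = sd > 0
        corr = np.corrcoef(mat[ok])
        idx = np.flatnonzero(ok)
        r2 = np.asarray(corr) ** 2
        ii, jj = np.triu_indices(len(idx), k=1)
        bad = r2[ii, jj] > anchor_r2_max
        for a, b in zip(ii[bad], jj[bad]):
            name_a = anchor_names[idx[a]]
            name_b = anchor_names[idx[b]]
            violations.append(
                Violation("anchor_pair_r2_above_maximum", name_a,
                          f"anchor pair ({name_a}, {name_b}) r^2 "
                          f"{r2[a, b]:.4f} > {anchor_r2_max}", float(r2[a, b]))
            )
    return violations


# ---------------------------------------------------------------------------
# subsetting


def subset_map(hmap: HaplotypeMap, mode: str, target_snp_count: int | None = None) -> HaplotypeMap:
    """Keep only singleton blocks, or the largest multi-SNP blocks.

    ``multiblocks_only`` adds blocks of size >= 2 largest-first (ties broken
    by anchor (chrom, pos)) until the cumulative SNP count first reaches or
    exceeds ``target_snp_count``.
    """
    if not hmap.blocks:
        raise MapStructureError("cannot subset an empty map")
    if mode == "singletons_only":
        return HaplotypeMap([b for b in hmap.blocks if b.size == 1])
    if mode != "multiblocks_only":
        raise ValueError(f"unknown subset mode {mode!r}")
    if target_snp_count is None:
        raise ValueError("multiblocks_only requires target_snp_count")
    candidates = sorted(
        (b for b in hmap.blocks if b.size >= 2),
        key=lambda b: (-b.size, b.anchor.key),
    )
    chosen: list[HaplotypeBlock] = []
    total = 0
    for block in candidates:
        if total >= target_snp_count:
            break
        chosen.append(block)
        total += block.size
    result = HaplotypeMap(chosen)
    if total < target_snp_count:
        msg = (f"target of {target_snp_count} SNPs unreachable: only {total} SNPs "
               f"in blocks of size >= 2")
        logger.warning(msg)
        result.warnings.append(msg)
    return result


def relabel_snp(snp: SnpRecord, **changes) -> SnpRecord:
    """Convenience for tests and builders: copy with field changes."""
    return replace(snp, **changes)
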