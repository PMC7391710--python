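"""Construct haplotype maps from a phased genotype panel.

Pipeline: candidate filtering (MAF floor, cross-population MAF stability),
windowed LD pruning to an independent anchor set, LD-score ordering of the
anchors, then greedy assignment of tightly linked SNPs into each anchor's
block. Also provides the per-locus expected-information utility that
motivates preferring common variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, MonomorphicSnpError
from .haplotype_map import (
    PHASE_MINUS,
    PHASE_PLUS,
    HaplotypeBlock,
    HaplotypeMap,
    SnpRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PanelSnp:
    """One bi-allelic, phased SNP in a panel. Haplotype columns code
    0 = major allele, 1 = minor allele."""

    chrom: str
    pos: int
    name: str
    major_allele: str
    minor_allele: str


class PhasedPanel:
    """A phased haplotype matrix plus per-SNP metadata.

    ``haplotypes`` has one row per haplotype (two per individual) and one
    column per SNP, entries in {0, 1} with 1 marking the minor allele.
    ``populations``, if given, labels each *individual*.
    """

    def __init__(
        self,
        snps: Sequence[PanelSnp],
        haplotypes: np.ndarray,
        populations: Sequence[str] | None = None,
    ):
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 2 or haplotypes.shape[1] != len(snps):
            raise ConfigurationError(
                f"haplotype matrix shape {haplotypes.shape} does not match "
                f"{len(snps)} SNPs"
            )
        if haplotypes.shape[0] % 2:
            raise ConfigurationError("haplotype count must be even (2 per individual)")
        if not np.isin(haplotypes, (0, 1)).all():
            raise ConfigurationError("haplotype entries must be 0 or 1")
        if populations is not None and len(populations) != haplotypes.shape[0] // 2:
            raise ConfigurationError("one population label per individual required")
        self.snps = tuple(snps)
        self.haplotypes = haplotypes
        self.populations = tuple(populations) if populations is not None else None
        self._name_index = {s.name: i for i, s in enumerate(self.snps)}
        if len(self._name_index) != len(self.snps):
            raise ConfigurationError("duplicate SNP names in panel")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def index_of(self, name: str) -> int:
        return self._name_index[name]

    def column(self, name: str) -> np.ndarray:
        return self.haplotypes[:, self._name_index[name]]

    def maf(self, name: str) -> float:
        """Empirical minor-allele frequency (frequency of 1s)."""
        return float(self.column(name).mean())

    def population_mafs(self, name: str) -> dict[str, float]:
        if self.populations is None:
            raise ConfigurationError("panel has no population labels")
        col = self.column(name)
        per_ind = col.reshape(-1, 2)
        out: dict[str, list] = {}
        for label, pair in zip(self.populations, per_ind):
            out.setdefault(label, []).append(pair)
        return {
            label: float(min(f := np.mean(pairs), 1 - f))
            for label, pairs in out.items()
        }

    def subset(self, names: Sequence[str]) -> "PhasedPanel":
        idx = [self._name_index[n] for n in names]
        return PhasedPanel(
            [self.snps[i] for i in idx], self.haplotypes[:, idx], self.populations
        )


class GeneticMap:
    """Piecewise-linear bp -> cM mapping per chromosome.

    Positions outside the knot range take the nearest knot's cM value.
    When no genetic map is available, callers approximate 1 cM as 1 Mb.
    """

    def __init__(self, knots: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._knots = {}
        for chrom, (pos, cm) in knots.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(pos)
            pos, cm = pos[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ConfigurationError(
                    f"genetic map for {chrom} is not monotone nondecreasing"
                )
            self._knots[chrom] = (pos, cm)

    @classmethod
    def from_file(cls, path) -> "GeneticMap":
        """Whitespace-delimited ``chrom pos cM`` (comment lines with #)."""
        knots: dict[str, tuple[list, list]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, cm = line.split()[:3]
                knots.setdefault(chrom, ([], []))
                knots[chrom][0].append(float(pos))
                knots[chrom][1].append(float(cm))
        return cls({c: (np.array(p), np.array(m)) for c, (p, m) in knots.items()})

    def cm(self, chrom: str, pos) -> np.ndarray:
        """Interpolated genetic position; np.interp clamps to end knots."""
        if chrom not in self._knots:
            raise ConfigurationError(f"no genetic map for chromosome {chrom}")
        xs, ys = self._knots[chrom]
        return np.interp(np.asarray(pos, dtype=float), xs, ys)


@dataclass(frozen=True)
class BuilderConfig:
    """Map-construction parameters; defaults follow the published pipeline."""

    min_maf: float = 0.10
    max_pop_maf_diff: float = 0.10
    anchor_r2_max: float = 0.10
    prune_window_bp: int = 10_000
    prune_slide_snps: int = 5
    member_r2_min: float = 0.85
    block_window_bp: int = 10_000_000
    ldscore_window_cm: float = 1.0

    def __post_init__(self):
        for name in ("min_maf", "max_pop_maf_diff", "anchor_r2_max", "member_r2_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        for name in ("prune_window_bp", "prune_slide_snps", "block_window_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.ldscore_window_cm <= 0:
            raise ConfigurationError("ldscore_window_cm must be positive")


# ---------------------------------------------------------------------------
# LD statistics


def pairwise_r2(panel: PhasedPanel, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of two allele-indicator columns.

    On phased 0/1 data this equals D^2 / (p_A p_a p_B p_b).
    """
    a = panel.column(snp_i).astype(float)
    b = panel.column(snp_j).astype(float)
    if a.std() == 0 or b.std() == 0:
        raise MonomorphicSnpError(
            f"r^2 undefined for monomorphic column ({snp_i} or {snp_j})"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def _r2_matrix(cols: np.ndarray) -> np.ndarray:
    """r^2 between all column pairs; monomorphic columns get r^2 = 0."""
    cols = cols.astype(float)
    sd = cols.std(axis=0)
    n = cols.shape[1]
    out = np.zeros((n, n))
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(cols[:, ok], rowvar=False)
        out[np.ix_(ok, ok)] = np.asarray(sub) ** 2
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# pipeline stages


def filter_candidates(panel: PhasedPanel, cfg: BuilderConfig) -> PhasedPanel:
    """Drop SNPs with global MAF below the floor or unstable MAF across
    populations (max minus min per-population MAF above the allowed gap).

    Panels without population labels skip the stability filter with a
    warning so single-population synthetic panels remain usable.
    """
    keep: list[str] = []
    check_pops = panel.populations is not None
    if not check_pops:
        warnings.warn(
            "panel has no population labels; skipping cross-population "
            "MAF-difference filter",
            stacklevel=2,
        )
    freqs = panel.haplotypes.mean(axis=0)
    for snp, f in zip(panel.snps, freqs):
        maf = min(float(f), 1.0 - float(f))
        if maf < cfg.min_maf:
            continue
        if check_pops:
            pop_mafs = panel.population_mafs(snp.name)
            if max(pop_mafs.values()) - min(pop_mafs.values()) > cfg.max_pop_maf_diff:
                continue
        keep.append(snp.name)
    logger.info("filter_candidates: retained %d / %d SNPs", len(keep), panel.n_snps)
    return panel.subset(keep)


def prune_anchors(panel: PhasedPanel, cfg: BuilderConfig) -> list[str]:
    """Windowed LD pruning to an independent anchor set.

    Windows of ``prune_window_bp`` are examined stepping
    ``prune_slide_snps`` SNPs at a time; while any surviving pair in the
    window has r^2 > ``anchor_r2_max``, the lower-MAF SNP of the first
    offending pair is dropped (ties: later position). Output preserves
    panel order.
    """
    kept = np.ones(panel.n_snps, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, snp in enumerate(panel.snps):
        by_chrom.setdefault(snp.chrom, []).append(i)
    freqs = panel.haplotypes.mean(axis=0)
    mafs = np.minimum(freqs, 1 - freqs)

    for chrom, idx_list in by_chrom.items():
        idx = np.array(idx_list)
        pos = np.array([panel.snps[i].pos for i in idx])
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        start = 0
        while start < len(idx):
            window_end = pos[start] + cfg.prune_window_bp
            n_window = int(np.searchsorted(pos, window_end, side="right")) - start
            in_window = [
                j for j in range(start, start + n_window) if kept[idx[j]]
            ]
            changed = True
            while changed and len(in_window) > 1:
                changed = False
                cols = panel.haplotypes[:, idx[in_window]]
                r2 = _r2_matrix(cols)
                for a in range(len(in_window)):
                    for b in range(a + 1, len(in_window)):
                        if r2[a, b] > cfg.anchor_r2_max:
                            ga, gb = idx[in_window[a]], idx[in_window[b]]
                            if mafs[ga] < mafs[gb]:
                                drop = ga
                            elif mafs[gb] < mafs[ga]:
                                drop = gb
                            else:  # tie: drop the later position
                                drop = max(ga, gb, key=lambda g: panel.snps[g].pos)
                            kept[drop] = False
                            in_window = [j for j in in_window if kept[idx[j]]]
                            changed = True
                            break
                    if changed:
                        break
            # literal 5-SNP slide when windows are dense; never skip past a
            # sparse window's unexamined successors
            start += max(1, min(cfg.prune_slide_snps, n_window))
    survivors = [s.name for i, s in enumerate(panel.snps) if kept[i]]
    logger.info("prune_anchors: %d anchors from %d SNPs", len(survivors), panel.n_snps)
    return survivors


def _genetic_positions(panel: PhasedPanel, chrom: str, pos: np.ndarray,
                       gmap: GeneticMap | None) -> np.ndarray:
    if gmap is None:
        return pos / 1e6  # 1 cM ~ 1 Mb fallback
    return gmap.cm(chrom, pos)


def ld_score(
    panel: PhasedPanel,
    snp: str,
    gmap: GeneticMap | None = None,
    window_cm: float = 1.0,
) -> float:
    """Sum of r^2 of ``snp`` with every panel SNP within +/- ``window_cm``,
    including the self term (1.0)."""
    i = panel.index_of(snp)
    target = panel.snps[i]
    same = [j for j, s in enumerate(panel.snps) if s.chrom == target.chrom]
    pos = np.array([panel.snps[j].pos for j in same], dtype=float)
    cm = _genetic_positions(panel, target.chrom, pos, gmap)
    center = _genetic_positions(panel, target.chrom, np.array([float(target.pos)]), gmap)[0]
    near = [j for j, c in zip(same, cm) if abs(c - center) <= window_cm]
    cols = panel.haplotypes[:, near].astype(float)
    me = panel.column(snp).astype(float)
    if me.std() == 0:
        raise MonomorphicSnpError(f"LD score undefined for monomorphic SNP {snp}")
    score = 0.0
    sd = cols.std(axis=0)
    ok = sd > 0
    if ok.any():
        centered = cols[:, ok] - cols[:, ok].mean(axis=0)
        mc = me - me.mean()
        r = (centered.T @ mc) / (len(me) * sd[ok] * me.std())
        score = float(np.sum(r * r))
    # monomorphic neighbours contribute nothing; self term is included via
    # the j == i column (r^2 exactly 1)
    return score


def expected_block_information(maf: float) -> float:
    """Expected per-locus LOD contribution -sum_g p(g) log10 p(g) under
    Hardy-Weinberg priors; maximal (1.5 log10 2) at maf 0.5."""
    if not 0.0 < maf <= 0.5:
        raise ConfigurationError(f"maf must be in (0, 0.5], got {maf}")
    f = maf
    p = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
    p = p[p > 0]
    return float(-(p * np.log10(p)).sum())


# ---------------------------------------------------------------------------
# block construction


def build_blocks(
    panel: PhasedPanel,
    anchors: Sequence[str],
    gmap: GeneticMap | None = None,
    cfg: BuilderConfig = BuilderConfig(),
) -> HaplotypeMap:
    """Greedy block assembly around anchors in descending LD-score order.

    A non-anchor SNP joins the first-processed (highest LD score) anchor
    for which r^2 >= ``member_r2_min`` within ``block_window_bp``; member
    phase is the sign of its allelic covariance with the anchor; the whole
    block uses the anchor's MAF.
    """
    anchor_set = set(anchors)
    scores = {
        name: ld_score(panel, name, gmap, cfg.ldscore_window_cm) for name in anchors
    }
    ordered = sorted(
        anchors,
        key=lambda n: (-scores[n], panel.snps[panel.index_of(n)].chrom,
                       panel.snps[panel.index_of(n)].pos),
    )
    claimed: set[str] = set(anchor_set)
    freqs = panel.haplotypes.mean(axis=0)
    blocks: list[HaplotypeBlock] = []
    by_chrom: dict[str, list[int]] = {}
    for i, snp in enumerate(panel.snps):
        by_chrom.setdefault(snp.chrom, []).append(i)

    for anchor_name in ordered:
        ai = panel.index_of(anchor_name)
        a_snp = panel.snps[ai]
        a_maf = min(float(freqs[ai]), 1 - float(freqs[ai]))
        a_col = panel.haplotypes[:, ai].astype(float)
        anchor_rec = SnpRecord(
            a_snp.chrom, a_snp.pos, a_snp.name, a_snp.major_allele,
            a_snp.minor_allele, a_maf, a_snp.name, PHASE_PLUS,
        )
        members: list[SnpRecord] = []
        cand = [
            j for j in by_chrom[a_snp.chrom]
            if panel.snps[j].name not in claimed
            and abs(panel.snps[j].pos - a_snp.pos) <= cfg.block_window_bp
        ]
        if cand:
            cols = panel.haplotypes[:, cand].astype(float)
            sd = cols.std(axis=0)
            a_sd = a_col.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = ((cols - cols.mean(axis=0)).T @ (a_col - a_col.mean())) / len(a_col)
                r = np.where(sd > 0, cov / (sd * a_sd), 0.0)
            r2 = r * r
            for j, rj, r2j in zip(cand, r, r2):
                if r2j >= cfg.member_r2_min:
                    m = panel.snps[j]
                    m_maf = min(float(freqs[j]), 1 - float(freqs[j]))
                    members.append(
                        SnpRecord(
                            m.chrom, m.pos, m.name, m.major_allele, m.minor_allele,
                            m_maf, a_snp.name,
                            PHASE_PLUS if rj >= 0 else PHASE_MINUS,
                        )
                    )
                    claimed.add(m.name)
        blocks.append(
            HaplotypeBlock(anchor_rec, (anchor_rec, *sorted(members, key=lambda s: s.key)))
        )
    return HaplotypeMap(blocks)


def build_map(
    panel: PhasedPanel,
    gmap: GeneticMap | None = None,
    cfg: BuilderConfig = BuilderConfig(),
) -> HaplotypeMap:
    """Full pipeline: filter -> prune -> greedy block building."""
    filtered = filter_candidates(panel, cfg)
    anchors = prune_anchors(filtered, cfg)
    return build_blocks(filtered, anchors, gmap, cfg)


# ---------------------------------------------------------------------------
# panel I/O


def panel_to_vcf(panel: PhasedPanel, path, sample_prefix: str = "IND") -> None:
    """Write the panel as a phased VCF (GT with '|' separators)."""
    from ._util import atomic_write

    n_ind = panel.n_haplotypes // 2
    samples = [f"{sample_prefix}{i:05d}" for i in range(n_ind)]
    contigs: dict[str, int] = {}
    for snp in panel.snps:
        contigs[snp.chrom] = max(contigs.get(snp.chrom, 0), snp.pos)
    with atomic_write(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldfingerprint-simdata\n")
        for chrom, maxpos in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1_000_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = sorted(range(panel.n_snps), key=lambda i: (panel.snps[i].chrom,
                                                           panel.snps[i].pos))
        for i in order:
            snp = panel.snps[i]
            col = panel.haplotypes[:, i]
            gts = "\t".join(f"{col[2 * j]}|{col[2 * j + 1]}" for j in range(n_ind))
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.name}\t{snp.major_allele}\t"
                     f"{snp.minor_allele}\t.\t.\t.\tGT\t{gts}\n")


def panel_from_vcf(path, populations_file=None) -> PhasedPanel:
    """Load a phased panel from VCF; requires '|'-separated GT fields.

    Multi-allelic records are rejected. ``populations_file`` is an optional
    two-column ``sample<TAB>population`` file.
    """
    import pysam

    snps: list[PanelSnp] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ConfigurationError(
                    f"panel VCF record {rec.chrom}:{rec.pos} is not bi-allelic"
                )
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ConfigurationError(
                    f"panel VCF record {rec.chrom}:{rec.pos} is not a SNP"
                )
            hap = np.empty(2 * len(sample_names), dtype=np.int8)
            for j, sample in enumerate(rec.samples.values()):
                if not sample.phased:
                    raise ConfigurationError(
                        f"unphased genotype at {rec.chrom}:{rec.pos}"
                    )
                alleles = sample["GT"]
                hap[2 * j] = alleles[0]
                hap[2 * j + 1] = alleles[1]
            name = rec.id or f"{rec.chrom}:{rec.pos}"
            snps.append(PanelSnp(rec.chrom, rec.pos, name, ref, alt))
            columns.append(hap)
    populations = None
    if populations_file is not None:
        mapping = {}
        with open(populations_file) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    sample, pop = line.split()[:2]
                    mapping[sample] = pop
        populations = [mapping[s] for s in sample_names]
    return PhasedPanel(snps, np.stack(columns, axis=1), populations)
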