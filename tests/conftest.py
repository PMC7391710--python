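import numpy as np
import pytest

from ldfingerprint.haplotype_map import HaplotypeBlock, HaplotypeMap, SnpRecord


def make_snp(chrom="1", pos=100, name="a1", major="A", minor="C", maf=0.3,
             anchor=None, phase="+"):
    return SnpRecord(chrom, pos, name, major, minor, maf, anchor or name, phase)


def make_block(anchor_name, pos, member_specs=(), maf=0.3, chrom="1"):
    """member_specs: iterable of (offset, name, phase)."""
    anchor = make_snp(chrom, pos, anchor_name, maf=maf)
    members = [anchor] + [
        make_snp(chrom, pos + off, name, major="G", minor="T", maf=maf,
                 anchor=anchor_name, phase=phase)
        for off, name, phase in member_specs
    ]
    return HaplotypeBlock(anchor, tuple(members))


@pytest.fixture
def tiny_map():
    """Two blocks, five SNPs, including a '-'-phased member."""
    b1 = make_block("a1", 100, [(50, "m1", "+"), (90, "m2", "-")], maf=0.25)
    b2 = make_block("a2", 50_000, [(70, "m3", "+")], maf=0.5)
    return HaplotypeMap([b1, b2])


@pytest.fixture
def small_map():
    from ldfingerprint.simdata import random_map

    return random_map(50, snps_per_block=3, seed=7, minus_phase_rate=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
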