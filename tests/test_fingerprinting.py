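import math

import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ldfingerprint.errors import (
    ChecksumMismatchError,
    ContigMismatchError,
    DuplicateSourceError,
    LdFingerprintError,
)
from ldfingerprint.fingerprinting import (
    Allele,
    AlleleObservation,
    BlockLikelihoods,
    Fingerprint,
    ReadFilterConfig,
    block_likelihoods,
    build_fingerprint,
    extract_observations,
    fingerprint_to_vcf,
    observation_likelihood,
    vcf_to_fingerprint,
)
from ldfingerprint.simdata import AssayModel, sample_individual, simulate_reads


# ---------------------------------------------------------------------------
# per-observation likelihood model

class TestObservationLikelihood:
    def test_major_given_aa(self):
        assert observation_likelihood(Allele.MAJOR, 0.01, "AA") == pytest.approx(0.99)

    def test_het_is_half_regardless_of_error(self):
        for e in (0.001, 0.01, 0.3):
            assert observation_likelihood(Allele.MAJOR, e, "AB") == 0.5
            assert observation_likelihood(Allele.MINOR, e, "AB") == 0.5

    def test_major_given_bb(self):
        assert observation_likelihood(Allele.MAJOR, 0.01, "BB") == pytest.approx(0.01)

    def test_minor_given_bb(self):
        assert observation_likelihood(Allele.MINOR, 0.01, "BB") == pytest.approx(0.99)

    @given(st.floats(min_value=1e-6, max_value=0.5),
           st.sampled_from(["AA", "AB", "BB"]))
    def test_normalization_over_alleles(self, e, genotype):
        total = (observation_likelihood(Allele.MAJOR, e, genotype)
                 + observation_likelihood(Allele.MINOR, e, genotype))
        assert total == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# per-block likelihoods

def obs(allele, e, source, block="a1"):
    return AlleleObservation(block, allele, e, source)


class TestBlockLikelihoods:
    def test_empty_is_zero(self):
        bl = block_likelihoods([])
        assert (bl.ll_aa, bl.ll_ab, bl.ll_bb, bl.n_observations) == (0, 0, 0, 0)

    def test_single_major_observation(self):
        bl = block_likelihoods([obs(Allele.MAJOR, 0.001, "r1")])
        assert bl.ll_aa == pytest.approx(math.log10(0.999))
        assert bl.ll_ab == pytest.approx(math.log10(0.5))
        assert bl.ll_bb == pytest.approx(math.log10(0.001))

    def test_three_observations_match_linear_space_oracle(self):
        # frozen from the brute-force product over Eq-style factors:
        # {MAJOR e=.01, MAJOR e=.01, MINOR e=.01}
        bl = block_likelihoods([
            obs(Allele.MAJOR, 0.01, "r1"),
            obs(Allele.MAJOR, 0.01, "r2"),
            obs(Allele.MINOR, 0.01, "r3"),
        ])
        assert bl.ll_aa == pytest.approx(-2.0087296108049, abs=1e-10)
        assert bl.ll_ab == pytest.approx(-0.9030899869919435, abs=1e-10)
        assert bl.ll_bb == pytest.approx(-4.00436480540245, abs=1e-10)

    def test_duplicate_source_rejected(self):
        with pytest.raises(DuplicateSourceError):
            block_likelihoods([obs(Allele.MAJOR, 0.01, "r1"),
                               obs(Allele.MINOR, 0.01, "r1")])

    def test_mixed_blocks_rejected(self):
        with pytest.raises(LdFingerprintError):
            block_likelihoods([obs(Allele.MAJOR, 0.01, "r1", block="a1"),
                               obs(Allele.MAJOR, 0.01, "r2", block="a2")])

    def test_factorization_over_disjoint_sources(self, rng):
        all_obs = [
            obs(Allele.MAJOR if rng.random() < 0.5 else Allele.MINOR,
                float(rng.uniform(1e-4, 0.4)), f"r{i}")
            for i in range(20)
        ]
        full = block_likelihoods(all_obs)
        l1 = block_likelihoods(all_obs[:7])
        l2 = block_likelihoods(all_obs[7:])
        np.testing.assert_allclose(full.array, l1.array + l2.array, atol=1e-10)

    def test_likelihoods_nonpositive(self):
        bl = block_likelihoods([obs(Allele.MINOR, 0.25, "r1")])
        assert (bl.array <= 0).all()

    def test_error_prob_clamped_range_enforced(self):
        with pytest.raises(LdFingerprintError):
            AlleleObservation("a1", Allele.MAJOR, 0.0, "r1")
        with pytest.raises(LdFingerprintError):
            AlleleObservation("a1", Allele.MAJOR, 0.7, "r1")


# ---------------------------------------------------------------------------
# observation extraction


def sam_read(header, *, name="r1", chrom="1", pos1=100, seq=None, base="A",
             offset=0, length=20, mq=60, bq=30, flag=0):
    """One aligned record placing ``base`` at reference position ``pos1``."""
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    if seq is None:
        s = ["T"] * length
        s[offset] = base
        seq = "".join(s)
    seg.query_sequence = seq
    seg.reference_name = chrom
    seg.reference_start = pos1 - 1 - offset
    seg.cigarstring = f"{len(seq)}M"
    seg.mapping_quality = mq
    quals = [bq] * len(seq)
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals)
    )
    seg.flag = flag
    return seg


@pytest.fixture
def header(tiny_map):
    from ldfingerprint.simdata import alignment_header

    return alignment_header(tiny_map)


class TestExtractObservations:
    # tiny_map: block a1 (anchor 1:100 A/C maf .25, m1 1:150 G/T '+',
    # m2 1:190 G/T '-'), block a2 (anchor 1:50000 A/C maf .5, m3 1:50070 '+')

    def test_simple_anchor_observation(self, tiny_map, header):
        reads = [sam_read(header, base="A", pos1=100)]
        (o,) = extract_observations(reads, tiny_map)
        assert o.block_id == "a1" and o.allele is Allele.MAJOR
        assert o.error_prob == pytest.approx(1e-3)

    def test_mapping_quality_bound_is_strict(self, tiny_map, header):
        reads = [sam_read(header, base="A", pos1=100, mq=20)]
        assert extract_observations(reads, tiny_map) == []
        reads = [sam_read(header, base="A", pos1=100, mq=21)]
        assert len(extract_observations(reads, tiny_map)) == 1

    def test_base_quality_bound_is_inclusive(self, tiny_map, header):
        assert extract_observations(
            [sam_read(header, base="A", pos1=100, bq=19)], tiny_map) == []
        assert len(extract_observations(
            [sam_read(header, base="A", pos1=100, bq=20)], tiny_map)) == 1

    def test_duplicate_flag_excluded(self, tiny_map, header):
        reads = [sam_read(header, base="A", pos1=100, flag=0x400)]
        assert extract_observations(reads, tiny_map) == []

    def test_secondary_flag_excluded(self, tiny_map, header):
        reads = [sam_read(header, base="A", pos1=100, flag=0x100)]
        assert extract_observations(reads, tiny_map) == []

    def test_filters_can_be_disabled(self, tiny_map, header):
        filters = ReadFilterConfig(exclude_duplicates=False, exclude_secondary=False)
        reads = [sam_read(header, base="A", pos1=100, flag=0x400)]
        assert len(extract_observations(reads, tiny_map, filters)) == 1

    def test_third_allele_and_n_skipped(self, tiny_map, header):
        for base in ("G", "N"):
            reads = [sam_read(header, base=base, pos1=100)]
            assert extract_observations(reads, tiny_map) == []

    def test_minus_phase_translation(self, tiny_map, header):
        # m2 at 1:190 is '-'-phased: its major (G) is evidence of the
        # anchor's MINOR allele
        (o,) = extract_observations([sam_read(header, base="G", pos1=190)], tiny_map)
        assert o.allele is Allele.MINOR and o.block_id == "a1"
        (o,) = extract_observations([sam_read(header, base="T", pos1=190)], tiny_map)
        assert o.allele is Allele.MAJOR

    def test_plus_phase_translation(self, tiny_map, header):
        (o,) = extract_observations([sam_read(header, base="G", pos1=150)], tiny_map)
        assert o.allele is Allele.MAJOR

    def test_read_covering_two_sites_one_observation(self, tiny_map, header):
        # one 60 bp read spanning 1:100 and 1:150 (same block)
        seq = ["T"] * 60
        seq[0] = "A"   # anchor site 100
        seq[50] = "G"  # member site 150
        seg = sam_read(header, seq="".join(seq), pos1=100, length=60)
        observations = extract_observations([seg], tiny_map)
        assert len(observations) == 1
        assert observations[0].block_id == "a1"

    def test_read_pair_one_observation_across_blocks(self, tiny_map, header):
        # mates over different blocks still yield one observation total,
        # taken at the first site in (chrom, pos) order
        r1 = sam_read(header, name="pair", base="A", pos1=50_000)
        r2 = sam_read(header, name="pair", base="A", pos1=100)
        observations = extract_observations([r1, r2], tiny_map)
        assert len(observations) == 1
        assert observations[0].block_id == "a1"  # 1:100 sorts first

    def test_overlapping_mates_agree_keep_higher_bq(self, tiny_map, header):
        r1 = sam_read(header, name="pair", base="A", pos1=100, bq=25)
        r2 = sam_read(header, name="pair", base="A", pos1=100, bq=35)
        (o,) = extract_observations([r1, r2], tiny_map)
        assert o.error_prob == pytest.approx(10 ** -3.5)

    def test_overlapping_mates_disagree_discard_site(self, tiny_map, header):
        r1 = sam_read(header, name="pair", base="A", pos1=100)
        r2 = sam_read(header, name="pair", base="C", pos1=100)
        assert extract_observations([r1, r2], tiny_map) == []

    def test_unmapped_only_input_empty(self, tiny_map, header):
        seg = pysam.AlignedSegment(header)
        seg.query_name = "u1"
        seg.flag = 0x4
        assert extract_observations([seg], tiny_map) == []

    def test_contig_mismatch_listed(self, tiny_map):
        bad_header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrZ", "LN": 1000}]}
        )
        seg = pysam.AlignedSegment(bad_header)
        seg.query_name = "r"
        seg.flag = 0x4
        with pytest.raises(ContigMismatchError, match="1"):
            extract_observations([seg], tiny_map)

    def test_filter_monotonicity_in_base_quality(self, tiny_map, header, rng):
        reads = [
            sam_read(header, name=f"r{i}", base="A", pos1=100,
                     bq=int(rng.integers(2, 45)))
            for i in range(60)
        ]
        counts = [
            len(extract_observations(
                reads, tiny_map, ReadFilterConfig(min_base_quality=q)))
            for q in range(0, 46, 5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_sam_file_round_trip(self, tiny_map, header, tmp_path):
        from ldfingerprint.simdata import write_sam

        reads = [sam_read(header, name=f"r{i}", base="A", pos1=100)
                 for i in range(5)]
        path = tmp_path / "reads.sam"
        write_sam(header, reads, path)
        assert len(extract_observations(str(path), tiny_map)) == 5


# ---------------------------------------------------------------------------
# fingerprints


class TestBuildFingerprint:
    def test_zero_reads_all_zero(self, tiny_map):
        fp = build_fingerprint([], tiny_map, sample_id="x")
        assert fp.n_covered_blocks == 0
        assert (fp.ll == 0).all()

    def test_homozygous_recovery(self, small_map):
        individual = sample_individual(small_map, seed=3)
        assay = AssayModel(depth_lambda=30, base_error_rate=0.001)
        header, reads = simulate_reads(individual, small_map, assay, seed=4)
        fp = build_fingerprint(reads, small_map, sample_id="hom")
        geno = individual.genotype
        agree = sum(
            fp.block(name).argmax_genotype() == ("AA", "AB", "BB")[geno[i]]
            for i, name in enumerate(small_map.anchor_names)
            if fp.block(name).n_observations > 0
        )
        covered = fp.n_covered_blocks
        assert covered >= 45 and agree / covered >= 0.99

    def test_split_additivity(self, small_map):
        individual = sample_individual(small_map, seed=5)
        header, reads = simulate_reads(
            individual, small_map, AssayModel(depth_lambda=10), seed=6
        )
        full = build_fingerprint(reads, small_map)
        h1 = build_fingerprint(reads[::2], small_map)
        h2 = build_fingerprint(reads[1::2], small_map)
        np.testing.assert_allclose(full.ll, h1.ll + h2.ll, atol=1e-9)
        np.testing.assert_array_equal(full.n_obs, h1.n_obs + h2.n_obs)


class TestVcfPersistence:
    @pytest.fixture
    def fingerprint(self, small_map):
        individual = sample_individual(small_map, seed=9)
        from ldfingerprint.simdata import simulate_fingerprint

        return simulate_fingerprint(individual, small_map, 20, 0.01, seed=10,
                                    sample_id="donorX")

    def test_round_trip_within_tolerance(self, fingerprint, small_map, tmp_path):
        path = tmp_path / "fp.vcf"
        fingerprint_to_vcf(fingerprint, small_map, path)
        back = vcf_to_fingerprint(path, small_map)
        assert back.sample_id == "donorX"
        assert np.abs(back.ll - fingerprint.ll).max() <= 1e-6
        np.testing.assert_array_equal(back.n_obs, fingerprint.n_obs)

    def test_output_is_valid_vcf(self, fingerprint, small_map, tmp_path):
        path = tmp_path / "fp.vcf"
        fingerprint_to_vcf(fingerprint, small_map, path)
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == len(small_map)

    def test_missing_anchor_becomes_empty_block(self, fingerprint, small_map, tmp_path):
        path = tmp_path / "fp.vcf"
        fingerprint_to_vcf(fingerprint, small_map, path)
        lines = path.read_text().splitlines()
        dropped = [l for l in lines if not l.startswith("#")][0].split("\t")[2]
        path.write_text("\n".join(l for l in lines
                                  if l.startswith("#") or f"\t{dropped}\t" not in l) + "\n")
        back = vcf_to_fingerprint(path, small_map)
        assert back.block(dropped).n_observations == 0
        assert (back.block(dropped).array == 0).all()

    def test_extra_records_ignored(self, fingerprint, small_map, tmp_path):
        path = tmp_path / "fp.vcf"
        fingerprint_to_vcf(fingerprint, small_map, path)
        with open(path, "a") as fh:
            fh.write("1\t999999999\tstray\tA\tC\t.\t.\tNOBS=3\tGT:GL\t0/0:0,0,0\n")
        back = vcf_to_fingerprint(path, small_map)
        assert np.abs(back.ll - fingerprint.ll).max() <= 1e-6

    def test_checksum_mismatch_refused(self, fingerprint, small_map, tiny_map, tmp_path):
        path = tmp_path / "fp.vcf"
        fingerprint_to_vcf(fingerprint, small_map, path)
        with pytest.raises(ChecksumMismatchError):
            vcf_to_fingerprint(path, tiny_map)

    def test_write_requires_matching_map(self, fingerprint, tiny_map, tmp_path):
        with pytest.raises(ChecksumMismatchError):
            fingerprint_to_vcf(fingerprint, tiny_map, tmp_path / "fp.vcf")
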