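"""Tally building from BAM, cycle conventions, and candidate enumeration."""

from pathlib import Path

import numpy as np
import pysam
import pytest

from servic4e.regions import TargetRegion
from servic4e.tally import (
    BASE_INDEX,
    build_tallies,
    enumerate_candidates,
    read_manifest,
    tallies_from_tsv,
    tallies_to_tsv,
)

from conftest import add_calls, make_region_tallies, spread_calls
from servic4e.tally import TallySet

REF = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACG"  # 47 bp


def write_bam(tmp_path: Path, reads, name="pool", contig="chrT", length=47):
    """reads: list of (qname, flag, pos0, seq, quals)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": length}]}
    unsorted = tmp_path / f"{name}.unsorted.bam"
    bam = tmp_path / f"{name}.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as af:
        for qname, flag, pos, seq, quals in reads:
            a = pysam.AlignedSegment(af.header)
            a.query_name = qname
            a.flag = flag
            a.reference_name = contig
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            af.write(a)
    pysam.sort("-o", str(bam), str(unsorted))
    pysam.index(str(bam))
    return bam


@pytest.fixture
def ref_fasta(tmp_path):
    fa = tmp_path / "ref.fa"
    fa.write_text(f">chrT\n{REF}\n")
    pysam.faidx(str(fa))
    return fa


REGION = [TargetRegion("chrT", 0, 47, "amp1")]


class TestBuildTallies:
    def test_single_plus_strand_read_identity(self, tmp_path, ref_fasta):
        bam = write_bam(tmp_path, [("r1", 0, 0, "G", [30])])
        ts = build_tallies([(1, str(bam))], REGION, 47, ref_fasta)
        pt = ts.regions["amp1"].position_tally(1, 0)
        assert pt.counts[BASE_INDEX["G"], 0, 0] == 1
        assert pt.qual_sums[BASE_INDEX["G"], 0, 0] == 30
        assert pt.counts.sum() == 1

    def test_minus_strand_cycle_reflection(self, tmp_path, ref_fasta):
        # one-base minus-strand read at query offset 0 -> cycle L = 47
        bam = write_bam(tmp_path, [("r1", 16, 0, "G", [30])])
        ts = build_tallies([(1, str(bam))], REGION, 47, ref_fasta)
        pt = ts.regions["amp1"].position_tally(1, 0)
        assert pt.counts[BASE_INDEX["G"], 46, 1] == 1
        assert pt.counts.sum() == 1

    def test_total_counts_match_per_read_walk(self, tmp_path, ref_fasta, rng):
        reads = []
        expected = np.zeros(47, dtype=int)  # per-position oracle
        for i in range(200):
            ln = int(rng.integers(5, 20))
            pos = int(rng.integers(0, 47 - ln + 1))
            flag = 16 if rng.random() < 0.5 else 0
            seq = "".join(rng.choice(list("ACGT"), size=ln))
            quals = [int(q) for q in rng.integers(5, 40, size=ln)]
            reads.append((f"r{i}", flag, pos, seq, quals))
            for j in range(ln):  # independent naive walk
                expected[pos + j] += 1
        bam = write_bam(tmp_path, reads)
        ts = build_tallies([(1, str(bam))], REGION, 47, ref_fasta)
        rt = ts.regions["amp1"]
        got = rt.counts.sum(axis=(0, 2, 3, 4))
        assert np.array_equal(got, expected)

    def test_order_independence(self, tmp_path, ref_fasta, rng):
        reads = []
        for i in range(50):
            pos = int(rng.integers(0, 40))
            reads.append((f"r{i}", 0, pos, "ACGTA", [20] * 5))
        bam1 = write_bam(tmp_path, reads, name="fwd")
        bam2 = write_bam(tmp_path, reads[::-1], name="rev")
        ts1 = build_tallies([(1, str(bam1))], REGION, 47, ref_fasta)
        ts2 = build_tallies([(1, str(bam2))], REGION, 47, ref_fasta)
        assert np.array_equal(ts1.regions["amp1"].counts, ts2.regions["amp1"].counts)

    def test_read_longer_than_declared_length_fails(self, tmp_path, ref_fasta):
        bam = write_bam(tmp_path, [("r1", 0, 0, "ACGTACGT", [30] * 8)])
        with pytest.raises(ValueError, match="cycle axis"):
            build_tallies([(1, str(bam))], REGION, 4, ref_fasta)

    def test_missing_index_fails_with_filename(self, tmp_path, ref_fasta):
        bam = write_bam(tmp_path, [("r1", 0, 0, "G", [30])])
        bam.with_suffix(".bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match=str(bam.name)):
            build_tallies([(1, str(bam))], REGION, 47, ref_fasta)

    def test_ambiguous_bases_dropped(self, tmp_path, ref_fasta):
        bam = write_bam(tmp_path, [("r1", 0, 0, "ANG", [30, 30, 30])])
        ts = build_tallies([(1, str(bam))], REGION, 47, ref_fasta)
        assert ts.regions["amp1"].counts.sum() == 2


class TestEnumerateCandidates:
    def _tallyset(self):
        rt = make_region_tallies(ref_seq="A" * 40, pool_ids=(1, 2, 3),
                                 read_length=8)
        return rt, TallySet([rt])

    def test_all_reference_positions_give_no_candidates(self):
        rt, ts = self._tallyset()
        for pool in (1, 2, 3):
            for pos in range(40):
                spread_calls(rt, pool, pos, "A", 5, 35.0, cycles=[1, 2])
        assert enumerate_candidates(ts, alleles_per_pool=8) == []

    def test_most_prominent_alt_only(self):
        rt, ts = self._tallyset()
        for pool in (1, 2, 3):
            for pos in range(40):
                spread_calls(rt, pool, pos, "A", 30, 35.0, cycles=[1, 2])
        # two alts in pool 1 at position 5: w ~0.02 (G) and ~0.005 (T)
        spread_calls(rt, 1, 5, "G", 10, 35.0, cycles=[1, 2])
        add_calls(rt, 1, 5, "T", 5, 35.0, cycle=3)
        cands = enumerate_candidates(ts, alleles_per_pool=8, waf_floor=0.001)
        assert [(c.pool_id, c.alt_base) for c in cands] == [(1, "G")]

    def test_floor_monotonicity(self):
        rt, ts = self._tallyset()
        for pool in (1, 2, 3):
            for pos in range(40):
                spread_calls(rt, pool, pos, "A", 20, 35.0, cycles=[1, 2])
        spread_calls(rt, 2, 7, "C", 1, 35.0, cycles=[1, 2, 3])
        spread_calls(rt, 3, 9, "G", 4, 35.0, cycles=[1, 2, 3, 4])
        floors = [0.0005, 0.005, 0.05, 0.5]
        sets = [
            {c.key for c in enumerate_candidates(ts, 8, waf_floor=f)}
            for f in floors
        ]
        for lo, hi in zip(sets, sets[1:]):
            assert hi <= lo  # raising the floor never adds candidates

    def test_trim_masks_region_extremes(self):
        rt, ts = self._tallyset()
        for pool in (1, 2, 3):
            for pos in range(40):
                spread_calls(rt, pool, pos, "A", 20, 35.0, cycles=[1, 2])
        spread_calls(rt, 1, 2, "G", 10, 35.0, cycles=[1, 2])   # inside trim
        spread_calls(rt, 1, 20, "G", 10, 35.0, cycles=[1, 2])  # callable
        cands = enumerate_candidates(ts, 8, waf_floor=0.01, trim=10)
        assert [c.position for c in cands] == [20]
        with pytest.raises(ValueError, match="trim"):
            enumerate_candidates(ts, 8, trim=20)

    def test_alleles_must_exceed_one(self, toy_tallyset):
        with pytest.raises(ValueError):
            enumerate_candidates(toy_tallyset, alleles_per_pool=1)


def test_tally_tsv_roundtrip(tmp_path):
    rt = make_region_tallies(ref_seq="ACGT" * 5, pool_ids=(1, 2), read_length=6)
    add_calls(rt, 1, 3, "G", 4, 31.5, cycle=2, strand="+")
    add_calls(rt, 2, 10, "T", 2, 18.0, cycle=6, strand="-")
    ts = TallySet([rt])
    path = tmp_path / "tallies.tsv"
    tallies_to_tsv(ts, path)
    ts2 = tallies_from_tsv(
        path, [rt.region], [1, 2], 6, {rt.region.label: rt.ref_seq}
    )
    rt2 = ts2.regions[rt.region.label]
    assert np.array_equal(rt.counts, rt2.counts)
    assert np.allclose(rt.qual_sums, rt2.qual_sums)


def test_read_manifest(tmp_path):
    p = tmp_path / "manifest.tsv"
    p.write_text("# pool\tbam\n1\ta.bam\n2\tb.bam\n")
    assert read_manifest(p) == [(1, "a.bam"), (2, "b.bam")]
    (tmp_path / "empty.tsv").write_text("")
    with pytest.raises(ValueError):
        read_manifest(tmp_path / "empty.tsv")
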