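"""Trimming, clonal removal, exact alignment (vs brute force), distribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medipseq.genome import WindowGrid
from medipseq.reads import (AlignmentRecord, KmerIndex, Read, align_exact,
                            build_coverage, coverage_summary,
                            deduplicate_clonal, distribute_repeats,
                            filter_organelle, read_fastq, records_from_sam,
                            revcomp, split_unique_multi, trim_reads)

BASES = "ACGT"


def _random_genome(rng, n):
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def brute_force_placements(read_seq, genome):
    """Scan every genome position on both strands for perfect matches."""
    out = []
    rc = revcomp(read_seq)
    for chrom, seq in genome.items():
        for i in range(len(seq) - len(read_seq) + 1):
            window = seq[i:i + len(read_seq)]
            if window == read_seq:
                out.append((chrom, i, "+"))
            if window == rc:
                out.append((chrom, i, "-"))
    return out


class TestTrimDedup:
    def test_trim_truncates_and_preserves_ids(self):
        reads = [Read("a", "A" * 36), Read("b", "C" * 32)]
        out, dropped = trim_reads(reads)
        assert dropped == 0
        assert [r.sequence for r in out] == ["A" * 32, "C" * 32]
        assert [r.id for r in out] == ["a", "b"]

    def test_short_reads_are_dropped_and_counted(self):
        out, dropped = trim_reads([Read("short", "ACGT" * 7)])  # 28 nt
        assert out == [] and dropped == 1

    def test_dedup_keeps_first_occurrence(self):
        reads = [Read("r1", "A" * 32), Read("r2", "A" * 32), Read("r3", "C" * 32)]
        out, removed = deduplicate_clonal(reads)
        assert removed == 1
        assert [r.id for r in out] == ["r1", "r3"]

    def test_dedup_collapses_to_distinct_sequences(self, rng):
        seqs = [_random_genome(rng, 32) for _ in range(10)]
        reads = [Read(f"r{i}", seqs[rng.integers(0, 10)]) for i in range(1000)]
        out, removed = deduplicate_clonal(reads)
        assert len(out) == len({r.sequence for r in reads})
        assert removed == 1000 - len(out)

    @given(st.lists(st.sampled_from(["A" * 32, "C" * 32, "ACGT" * 8]),
                    max_size=30))
    @settings(deadline=None, max_examples=25)
    def test_dedup_is_idempotent(self, seqs):
        reads = [Read(f"r{i}", s) for i, s in enumerate(seqs)]
        once, _ = deduplicate_clonal(reads)
        twice, removed = deduplicate_clonal(once)
        assert twice == once and removed == 0


class TestAlignExact:
    def test_agrees_with_brute_force_scan_on_toy_genome(self, rng):
        """Placement-completeness oracle over a <=10 kb genome."""
        genome = {"c1": _random_genome(rng, 4000), "c2": _random_genome(rng, 2000)}
        # plant an exact 3-copy repeat
        unit = _random_genome(rng, 200)
        genome["c1"] = genome["c1"][:500] + unit + genome["c1"][700:1500] + \
            unit + genome["c1"][1700:]
        genome["c2"] = genome["c2"][:300] + unit + genome["c2"][500:]
        index = KmerIndex(genome)
        reads = []
        for i in range(60):
            chrom = "c1" if rng.random() < 0.7 else "c2"
            pos = int(rng.integers(0, len(genome[chrom]) - 32))
            seq = genome[chrom][pos:pos + 32]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(Read(f"r{i}", seq))
        reads.append(Read("novel", "ACGT" * 8))
        records, unmapped = align_exact(reads, index)
        by_id = {r.read_id: r for r in records}
        for r in reads:
            expected = sorted(brute_force_placements(r.sequence, genome))
            if expected:
                assert sorted(by_id[r.id].placements) == expected, r.id
            else:
                assert r.id not in by_id

    def test_read_with_n_is_unmapped(self, rng):
        genome = {"c": _random_genome(rng, 500)}
        seq = genome["c"][:31] + "N"
        records, unmapped = align_exact([Read("n", seq)], KmerIndex(genome))
        assert records == [] and unmapped == 1

    def test_reverse_complement_maps_to_minus_strand(self, rng):
        genome = {"c": _random_genome(rng, 500)}
        seq = revcomp(genome["c"][100:132])
        records, _ = align_exact([Read("rc", seq)], KmerIndex(genome))
        assert records[0].placements == [("c", 100, "-")]

    def test_planted_repeat_multimaps_to_all_copies(self):
        rng = np.random.default_rng(4)
        unit = _random_genome(rng, 100)
        genome = {"c": _random_genome(rng, 200) + unit + _random_genome(rng, 200)
                  + unit + _random_genome(rng, 100) + unit}
        read = Read("rep", unit[10:42])
        records, _ = align_exact([read], KmerIndex(genome))
        assert records[0].n_placements == 3
        # exact expectation from the brute-force oracle
        assert sorted(records[0].placements) == sorted(
            brute_force_placements(read.sequence, genome))


class TestOrganelleAndSplit:
    def test_organelle_only_read_removed_but_dual_read_kept(self, rng):
        nuc = _random_genome(rng, 600)
        chl = _random_genome(rng, 400)
        shared = _random_genome(rng, 32)
        genome = {"chr1": nuc + shared, "chloroplast": chl + shared}
        index = KmerIndex(genome)
        reads = [Read("chl_only", chl[50:82]), Read("dual", shared),
                 Read("nuc_only", nuc[100:132])]
        records, _ = align_exact(reads, index)
        kept, removed = filter_organelle(records, {"chloroplast"})
        assert removed == 1
        by_id = {r.read_id: r for r in kept}
        assert set(by_id) == {"dual", "nuc_only"}
        assert all(c != "chloroplast" for c, _, _ in by_id["dual"].placements)

    def test_no_organelle_index_is_identity(self):
        recs = [AlignmentRecord("r", [("c", 0, "+")])]
        kept, removed = filter_organelle(recs, set())
        assert kept == recs and removed == 0

    def test_split_partition_is_exhaustive_and_disjoint(self):
        records = [AlignmentRecord("u", [("c", 0, "+")]),
                   AlignmentRecord("m", [("c", 0, "+"), ("c", 50, "-")])]
        unique, multi = split_unique_multi(records)
        assert [r.read_id for r in unique] == ["u"]
        assert [r.read_id for r in multi] == ["m"]
        assert split_unique_multi([]) == ([], [])


class TestDistribution:
    def test_equal_division_among_placements(self):
        grid = WindowGrid({"c": 4000}, 1000)
        rec = AlignmentRecord("r", [("c", 0, "+"), ("c", 1000, "+"),
                                    ("c", 2000, "+"), ("c", 3000, "+")])
        counts = distribute_repeats([rec], grid)
        assert np.allclose(counts, 0.25)

    def test_two_placements_in_same_window_sum(self):
        grid = WindowGrid({"c": 2000}, 1000)
        rec = AlignmentRecord("r", [("c", 10, "+"), ("c", 500, "-")])
        counts = distribute_repeats([rec], grid)
        assert counts[0] == pytest.approx(1.0) and counts[1] == 0

    def test_mass_conservation_over_random_records(self, rng):
        grid = WindowGrid({"c1": 50_000, "c2": 30_000}, 1000)
        records = []
        for i in range(100):
            n = int(rng.integers(2, 6))
            placements = []
            while len(placements) < n:
                chrom = "c1" if rng.random() < 0.5 else "c2"
                p = (chrom, int(rng.integers(0, grid.chrom_lengths[chrom] - 32)), "+")
                if p not in placements:
                    placements.append(p)
            records.append(AlignmentRecord(f"m{i}", placements))
        counts = distribute_repeats(records, grid)
        assert counts.sum() == pytest.approx(100, abs=1e-9)


class TestCoverage:
    def test_single_read_breadth(self):
        rec = AlignmentRecord("r", [("c", 0, "+")])
        track = build_coverage([rec], [], {"c": 1000})
        summary = coverage_summary(track)
        assert summary["unique"]["breadth_pct"] == pytest.approx(3.2)

    def test_empty_tracks_report_zero(self):
        track = build_coverage([], [], {"c": 1000})
        summary = coverage_summary(track)
        assert summary["unique"]["breadth_pct"] == 0
        assert summary["unique"]["mean_depth_covered"] == 0

    def test_uniform_two_x_simulation_depth(self, rng):
        """Tiling a chromosome twice end-to-end gives mean depth 2 exactly."""
        n = 6400
        records = [AlignmentRecord(f"r{i}", [("c", p, "+")])
                   for i, p in enumerate(list(range(0, n, 32)) * 2)]
        track = build_coverage(records, [], {"c": n})
        summary = coverage_summary(track)
        assert summary["unique"]["mean_depth_covered"] == pytest.approx(2.0, rel=0.05)

    def test_minus_strand_covers_same_bases_as_plus(self):
        plus = build_coverage([AlignmentRecord("r", [("c", 40, "+")])], [],
                              {"c": 200})
        minus = build_coverage([AlignmentRecord("r", [("c", 40, "-")])], [],
                               {"c": 200})
        assert np.array_equal(plus.unique["c"], minus.unique["c"])


class TestIO:
    def test_fastq_round_trip(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n@r2\nTTTTAAAA\n+\nIIIIIIII\n")
        reads = read_fastq(p)
        assert [(r.id, r.sequence) for r in reads] == [
            ("r1", "ACGTACGT"), ("r2", "TTTTAAAA")]

    def test_sam_ingest_groups_hits_per_read(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "multi\t0\tchr1\t11\t0\t32M\t*\t0\t0\t" + "A" * 32 + "\t*\n"
            "multi\t16\tchr1\t101\t0\t32M\t*\t0\t0\t" + "A" * 32 + "\t*\n"
            "uniq\t0\tchr1\t201\t0\t32M\t*\t0\t0\t" + "C" * 32 + "\t*\n"
            "lost\t4\t*\t0\t0\t*\t*\t0\t0\t" + "G" * 32 + "\t*\n")
        records, unmapped = records_from_sam(sam)
        by_id = {r.read_id: r for r in records}
        assert by_id["multi"].placements == [("chr1", 10, "+"), ("chr1", 100, "-")]
        assert by_id["uniq"].n_placements == 1
        assert unmapped == 1
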