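"""Read QC, unique-placement mapping and the coverage/read-depth features."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import brute_force_unique_map, per_base_features
from wfinder._util import revcomp, rng_stream
from wfinder.read_align import (
    ReadPlacement,
    ShortRead,
    compute_features,
    dedupe_reads,
    filter_low_complexity,
    ingest_sam,
    map_reads_unique,
    map_reads_unique_detailed,
    possible_placements,
    write_sam,
)
from wfinder.reference_prep import MaskedContig


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestReadQC:
    def test_dedupe_keeps_first_occurrence(self):
        reads = [ShortRead("a", "AAAT"), ShortRead("b", "AAAT"), ShortRead("c", "CCCG")]
        out = dedupe_reads(reads)
        assert [r.id for r in out] == ["a", "c"]

    def test_dedupe_distinct_is_identity(self):
        reads = [ShortRead(str(i), s) for i, s in enumerate(["ACGT", "TGCA", "GGCC"])]
        assert dedupe_reads(reads) == reads

    def test_dedupe_many_copies(self):
        # set-of-strings oracle: 10 copies each of 3 sequences -> 3 reads
        seqs = ["ACGTACGT", "TTTTACGT", "CCCCACGT"]
        reads = [ShortRead(f"r{i}_{j}", s) for j, s in enumerate(seqs) for i in range(10)]
        out = dedupe_reads(reads)
        assert sorted(r.seq for r in out) == sorted(set(s for s in seqs))

    def test_homopolymer_removed(self):
        assert filter_low_complexity([ShortRead("a", "A" * 36)], 0.8) == []

    def test_balanced_read_retained(self):
        r = ShortRead("a", "ACGT" * 9)
        assert filter_low_complexity([r], 0.8) == [r]

    def test_mono_fraction_boundary(self):
        # 30/36 = 0.8333: removed at 0.8, retained at 0.85
        r = ShortRead("a", "A" * 30 + "CGTCGT")
        assert filter_low_complexity([r], 0.8) == []
        assert filter_low_complexity([r], 0.85) == [r]


class TestMapReadsUnique:
    R = 36

    def _contig(self, seed, n=2000, mask=None):
        return MaskedContig("ref", random_seq(rng_stream(seed, "map-ref"), n), mask)

    def test_exact_unique_match(self):
        c = self._contig(0)
        read = ShortRead("r", c.seq[100:136])
        (p,) = map_reads_unique([read], [c])
        assert (p.contig_id, p.start, p.mismatches, p.strand) == ("ref", 100, 0, "+")

    def test_two_exact_loci_is_ambiguous(self):
        rng = rng_stream(1, "map")
        block = random_seq(rng, 36)
        seq = random_seq(rng, 200) + block + random_seq(rng, 200) + block + random_seq(rng, 200)
        c = MaskedContig("ref", seq)
        placements, summary = map_reads_unique_detailed([ShortRead("r", block)], [c])
        assert placements == [] and summary["n_ambiguous"] == 1

    def test_strictly_better_placement_wins(self):
        rng = rng_stream(2, "map")
        block = random_seq(rng, 36)
        mutate1 = block[:10] + ("A" if block[10] != "A" else "C") + block[11:]
        mutate2 = (block[:5] + ("G" if block[5] != "G" else "T") + block[6:20]
                   + ("G" if block[20] != "G" else "T") + block[21:])
        seq = random_seq(rng, 150) + mutate1 + random_seq(rng, 150) + mutate2 + random_seq(rng, 150)
        c = MaskedContig("ref", seq)
        (p,) = map_reads_unique([ShortRead("r", block)], [c], max_mismatches=2)
        assert (p.start, p.mismatches) == (150, 1)

    def test_reverse_strand_placement(self):
        c = self._contig(3)
        read = ShortRead("r", revcomp(c.seq[500:536]))
        (p,) = map_reads_unique([read], [c])
        assert (p.start, p.strand, p.mismatches) == (500, "-", 0)

    def test_placement_overlapping_mask_discarded(self):
        c0 = self._contig(4)
        mask = np.zeros(len(c0), dtype=bool)
        mask[110:120] = True
        c = MaskedContig("ref", c0.seq, mask)
        read = ShortRead("r", c0.seq[100:136])  # spans masked bases
        placements, summary = map_reads_unique_detailed([read], [c])
        assert placements == [] and summary["n_no_hit"] == 1

    def test_read_with_n_dropped(self):
        c = self._contig(5)
        placements, summary = map_reads_unique_detailed(
            [ShortRead("r", "N" + c.seq[100:135])], [c])
        assert placements == [] and summary["n_invalid"] == 1

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_agrees_with_hamming_oracle(self, max_mm, seed):
        """Exact agreement with the sliding-window scan, ambiguity included."""
        rng = rng_stream(seed, "map-oracle")
        block = random_seq(rng, 60)
        contigs = []
        for i in range(3):
            seq = random_seq(rng, int(rng.integers(500, 1500)))
            pos = int(rng.integers(0, len(seq) - 60))
            seq = seq[:pos] + block + seq[pos + 60:]  # shared block -> ambiguity
            mask = rng.random(len(seq)) < 0.03
            contigs.append(MaskedContig(f"c{i}", seq, mask))
        reads = []
        for j in range(40):
            ci = int(rng.integers(0, 3))
            src = contigs[ci].seq
            start = int(rng.integers(0, len(src) - 36))
            s = src[start : start + 36]
            codes = list(s)
            for site in rng.choice(36, size=int(rng.integers(0, 4)), replace=False):
                codes[site] = "ACGT"[int(rng.integers(0, 4))]
            s = "".join(codes)
            if rng.random() < 0.5:
                s = revcomp(s)
            reads.append(ShortRead(f"r{j}", s))
        reads.append(ShortRead("random", random_seq(rng, 36)))

        expected = brute_force_unique_map(reads, contigs, max_mm)
        placements = map_reads_unique(reads, contigs, max_mismatches=max_mm)
        got = {p.read_id: (p.contig_id, p.start, p.strand, p.mismatches) for p in placements}
        exp_placed = {k: v for k, v in expected.items() if v is not None}
        assert got == exp_placed


class TestPossiblePlacements:
    def test_single_segment(self):
        c = MaskedContig("c", "A" * 100)
        assert possible_placements(c, 36) == 65

    def test_short_segment_contributes_zero(self):
        mask = np.zeros(140, dtype=bool)
        mask[100:105] = True  # segments of 100 and 35
        c = MaskedContig("c", "A" * 140, mask)
        assert possible_placements(c, 36) == 65

    def test_boundary_segments(self):
        mask = np.zeros(73, dtype=bool)
        mask[36] = True  # segments [36, 36]
        c = MaskedContig("c", "A" * 73, mask)
        assert possible_placements(c, 36) == 2


class TestComputeFeatures:
    def _contig(self):
        return MaskedContig("c", random_seq(rng_stream(20, "feat"), 100))

    def test_single_read(self):
        c = self._contig()
        fv = compute_features(c, [ReadPlacement("r", "c", 0, 0)], 36)
        assert fv.x1 == pytest.approx(0.36)
        assert fv.x2 == pytest.approx(1 / 65)
        assert fv.eligible

    def test_zero_reads_is_w_signature(self):
        fv = compute_features(self._contig(), [], 36)
        assert (fv.x1, fv.x2, fv.n_reads) == (0.0, 0.0, 0)

    def test_overlapping_reads_against_per_base_oracle(self):
        c = self._contig()
        placements = [ReadPlacement("r1", "c", 0, 0), ReadPlacement("r2", "c", 10, 0)]
        fv = compute_features(c, placements, 36)
        x1, x2 = per_base_features(c, placements, 36)
        assert fv.x1 == pytest.approx(x1) == pytest.approx(0.46)
        assert fv.x2 == pytest.approx(x2) == pytest.approx(2 / 65)

    def test_ineligible_contig_flagged(self):
        c = MaskedContig("c", "A" * 30)  # shorter than a read
        fv = compute_features(c, [], 36)
        assert not fv.eligible and fv.possible_placements == 0

    def test_wrong_contig_placement_rejected(self):
        with pytest.raises(ValueError, match="passed to contig"):
            compute_features(self._contig(), [ReadPlacement("r", "other", 0, 0)], 36)

    def test_adding_a_placement_never_decreases_features(self):
        rng = rng_stream(21, "feat-mono")
        c = MaskedContig("c", random_seq(rng, 500))
        placements = []
        last = (0.0, 0.0)
        for start in rng.integers(0, 464, size=15):
            placements.append(ReadPlacement(f"r{len(placements)}", "c", int(start), 0))
            fv = compute_features(c, placements, 36)
            assert fv.x1 >= last[0] and fv.x2 >= last[1]
            last = (fv.x1, fv.x2)


class TestSamIO:
    def test_round_trip(self, tmp_path):
        rng = rng_stream(30, "sam")
        contigs = [MaskedContig("c1", random_seq(rng, 300)),
                   MaskedContig("c2", random_seq(rng, 200))]
        placements = [
            ReadPlacement("r1", "c1", 10, 0, "+"),
            ReadPlacement("r2", "c2", 50, 2, "-"),
        ]
        path = tmp_path / "out.sam"
        write_sam(placements, contigs, path, read_len=36)
        back = ingest_sam(path, contigs)
        assert back == placements

    def test_filtering_and_errors(self, tmp_path):
        header = "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:300\n"
        body = (
            "r1\t0\tc1\t11\t30\t36M\t*\t0\t0\t*\t*\n"      # primary, MAPQ 30
            "r2\t0\tc1\t21\t30\t36M\t*\t0\t0\t*\t*\n"
            "r3\t0\tc1\t31\t30\t36M\t*\t0\t0\t*\t*\n"
            "r4\t0\tc1\t41\t0\t36M\t*\t0\t0\t*\t*\n"       # MAPQ 0 -> dropped
            "r5\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"           # unmapped
            "r6\t256\tc1\t51\t30\t36M\t*\t0\t0\t*\t*\n"    # secondary
        )
        path = tmp_path / "in.sam"
        path.write_text(header + body)
        contigs = [MaskedContig("c1", "A" * 300)]
        placements = ingest_sam(path, contigs, min_mapping_quality=1)
        assert [p.read_id for p in placements] == ["r1", "r2", "r3"]
        assert placements[0].start == 10  # SAM is 1-based

    def test_empty_body(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:c1\tLN:300\n")
        assert ingest_sam(path, [MaskedContig("c1", "A" * 300)]) == []

    def test_unknown_contig_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:cX\tLN:300\n"
                        "r1\t0\tcX\t11\t30\t36M\t*\t0\t0\t*\t*\n")
        with pytest.raises(ValueError, match="absent from reference"):
            ingest_sam(path, [MaskedContig("c1", "A" * 300)])


class TestSyntheticSeparation:
    def test_w_contigs_collect_no_reads(self, small_sim):
        """In a clean ZZ experiment, W features sit at exactly (0, 0)."""
        w = small_sim.features.query("label == 'W'")
        assert (w["x1"] == 0).all() and (w["x2"] == 0).all()

    def test_w_means_below_nonw_tail(self, small_sim):
        nonw = small_sim.features.query("label == 'NONW' and eligible")
        w = small_sim.features.query("label == 'W'")
        for feat in ("x1", "x2"):
            assert w[feat].mean() < np.quantile(nonw[feat], 0.001)

    def test_read_depth_uniform_across_eligible_contigs(self, small_sim):
        """Uniform sampling: per-contig read depth is flat in expectation."""
        nonw = small_sim.features.query("label == 'NONW' and eligible")
        x2 = nonw["x2"].to_numpy()
        # Monte-Carlo error band: every contig's depth within 6 SD of the mean
        counts = nonw["n_reads"].to_numpy()
        rel_sd = 1 / np.sqrt(np.maximum(counts, 1))
        assert (np.abs(x2 - x2.mean()) <= 6 * rel_sd * x2.mean() + 1e-3).all()
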