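"""Masking, duplicate detection and short-segment filtering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_duplicate_mask
from wfinder._util import revcomp, rng_stream
from wfinder.reference_prep import (
    MaskedContig,
    MaskInterval,
    apply_mask,
    drop_short_segments,
    find_duplicate_regions,
    read_bed,
    read_fasta,
    unmasked_length,
    write_bed,
    write_fasta_hardmasked,
)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def masked_bases(contigs) -> int:
    return int(sum(c.mask.sum() for c in contigs))


class TestApplyMask:
    def test_single_interval_masks_exact_range(self):
        rng = rng_stream(0, "apply-mask")
        c = MaskedContig("c1", random_seq(rng, 100))
        (out,) = apply_mask([c], [MaskInterval("c1", 10, 20)])
        assert out.mask[10:20].all()
        assert unmasked_length(out) == 90

    def test_empty_interval_list_is_identity(self):
        rng = rng_stream(1, "apply-mask")
        c = MaskedContig("c1", random_seq(rng, 50))
        (out,) = apply_mask([c], [])
        assert not out.mask.any()
        assert out.seq == c.seq

    def test_overlapping_intervals_union(self):
        # brute-force per-base union oracle: [0,30) | [20,50) = 50 bases
        rng = rng_stream(2, "apply-mask")
        c = MaskedContig("c1", random_seq(rng, 100))
        intervals = [MaskInterval("c1", 0, 30), MaskInterval("c1", 20, 50)]
        expected = np.zeros(100, dtype=bool)
        for iv in intervals:
            expected[iv.start : iv.end] = True
        (out,) = apply_mask([c], intervals)
        assert int(out.mask.sum()) == int(expected.sum()) == 50
        assert (out.mask == expected).all()

    def test_unknown_contig_and_out_of_bounds_are_hard_errors(self):
        c = MaskedContig("c1", "ACGT" * 10)
        with pytest.raises(KeyError, match="nope"):
            apply_mask([c], [MaskInterval("nope", 0, 5)])
        with pytest.raises(ValueError, match="out of bounds"):
            apply_mask([c], [MaskInterval("c1", 30, 60)])

    def test_preserves_existing_mask(self):
        c = MaskedContig("c1", "ACGT" * 25, mask=np.arange(100) < 5)
        (out,) = apply_mask([c], [MaskInterval("c1", 50, 60)])
        assert out.mask[:5].all() and out.mask[50:60].all()

    @given(st.lists(st.tuples(st.integers(0, 99), st.integers(1, 30)), max_size=6))
    def test_union_matches_per_base_oracle(self, spans):
        intervals = [MaskInterval("c", s, min(s + w, 100)) for s, w in spans if s < 100]
        c = MaskedContig("c", "A" * 100)
        expected = np.zeros(100, dtype=bool)
        for iv in intervals:
            expected[iv.start : iv.end] = True
        (out,) = apply_mask([c], intervals)
        assert (out.mask == expected).all()


class TestContigInvariants:
    def test_n_bases_always_masked(self):
        c = MaskedContig("c", "ACGTNNACGT")
        assert c.mask[4:6].all() and not c.mask[:4].any()

    def test_mask_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask length"):
            MaskedContig("c", "ACGT", mask=np.zeros(3, dtype=bool))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            MaskedContig("c", "ACGT", label="X")


class TestFindDuplicateRegions:
    def _plant(self, rng, lengths, block_len, loci):
        """Random contigs with one repeated block planted at the given loci."""
        contigs = [MaskedContig(f"c{i}", random_seq(rng, n)) for i, n in enumerate(lengths)]
        block = random_seq(rng, block_len)
        out = []
        seqs = [list(c.seq) for c in contigs]
        for ci, pos in loci:
            seqs[ci][pos : pos + block_len] = block
        return [MaskedContig(c.id, "".join(s)) for c, s in zip(contigs, seqs)]

    def test_60bp_block_at_two_loci_reported(self):
        rng = rng_stream(3, "dup")
        contigs = self._plant(rng, [400], 60, [(0, 50), (0, 300)])
        intervals = find_duplicate_regions(contigs, min_len=50)
        covered = sorted((iv.start, iv.end) for iv in intervals)
        assert covered == [(50, 110), (300, 360)]

    def test_40bp_block_not_reported(self):
        # threshold is strict: only repeats *longer than* min_len qualify
        rng = rng_stream(4, "dup")
        contigs = self._plant(rng, [400], 40, [(0, 50), (0, 300)])
        assert find_duplicate_regions(contigs, min_len=50) == []

    def test_55bp_block_three_loci_two_contigs(self):
        rng = rng_stream(5, "dup")
        contigs = self._plant(rng, [600, 600], 55, [(0, 100), (0, 400), (1, 200)])
        intervals = find_duplicate_regions(contigs, min_len=50)
        expected_mask = brute_duplicate_mask(contigs, 50)
        got = {c.id: np.zeros(len(c), dtype=bool) for c in contigs}
        for iv in intervals:
            got[iv.contig_id][iv.start : iv.end] = True
        for c in contigs:
            assert (got[c.id] == expected_mask[c.id]).all()
        assert len(intervals) == 3

    def test_reverse_complement_copy_detected(self):
        rng = rng_stream(6, "dup")
        block = random_seq(rng, 70)
        left, right = random_seq(rng, 150), random_seq(rng, 150)
        c = MaskedContig("c", left + block + random_seq(rng, 100) + revcomp(block) + right)
        intervals = find_duplicate_regions([c], min_len=50)
        covered = np.zeros(len(c), dtype=bool)
        for iv in intervals:
            covered[iv.start : iv.end] = True
        assert covered[150 : 150 + 70].all()
        assert covered[320 : 320 + 70].all()

    def test_masked_copies_do_not_count(self):
        rng = rng_stream(7, "dup")
        contigs = self._plant(rng, [500], 80, [(0, 50), (0, 300)])
        mask = np.zeros(500, dtype=bool)
        mask[300:380] = True  # second copy hidden
        c = MaskedContig("c0", contigs[0].seq, mask)
        assert find_duplicate_regions([c], min_len=50) == []

    @pytest.mark.parametrize("min_len", [10, 50, 100])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_substring_oracle_on_random_genomes(self, min_len, seed):
        rng = rng_stream(seed, f"dup-prop-{min_len}")
        contigs = []
        for i in range(3):
            n = int(rng.integers(200, 1500))
            seq = random_seq(rng, n)
            mask = rng.random(n) < 0.05
            contigs.append(MaskedContig(f"c{i}", seq, mask))
        # plant a shared block so there is signal
        block = random_seq(rng, min_len + 15)
        s0 = contigs[0].seq[: 50] + block + contigs[0].seq[50 + len(block):]
        s1 = contigs[1].seq[: 20] + block + contigs[1].seq[20 + len(block):]
        contigs[0] = MaskedContig("c0", s0, contigs[0].mask)
        contigs[1] = MaskedContig("c1", s1, contigs[1].mask)
        expected = brute_duplicate_mask(contigs, min_len)
        intervals = find_duplicate_regions(contigs, min_len=min_len)
        got = {c.id: np.zeros(len(c), dtype=bool) for c in contigs}
        for iv in intervals:
            got[iv.contig_id][iv.start : iv.end] = True
        for c in contigs:
            np.testing.assert_array_equal(got[c.id], expected[c.id])


class TestDropShortSegments:
    def _with_segments(self, seg_lens, gap=5):
        parts, mask = [], []
        rng = rng_stream(8, "segments")
        for n in seg_lens:
            parts.append(random_seq(rng, n))
            mask.extend([False] * n)
            parts.append(random_seq(rng, gap))
            mask.extend([True] * gap)
        return MaskedContig("c", "".join(parts), np.array(mask, dtype=bool))

    def test_boundary_at_min_len(self):
        c = self._with_segments([49, 50, 200])
        out = drop_short_segments(c, min_len=50)
        assert [e - s for s, e in out.unmasked_segments()] == [50, 200]

    def test_fully_masked_unchanged(self):
        c = MaskedContig("c", "ACGT" * 25, np.ones(100, dtype=bool))
        out = drop_short_segments(c)
        assert out.mask.all()

    def test_all_short_islands_removed(self):
        c = self._with_segments([10] * 8)
        assert unmasked_length(drop_short_segments(c, min_len=50)) == 0

    def test_idempotent(self):
        c = self._with_segments([30, 60, 49, 120])
        once = drop_short_segments(c, min_len=50)
        twice = drop_short_segments(once, min_len=50)
        assert (once.mask == twice.mask).all()

    def test_unmasked_length_composition(self):
        c = self._with_segments([49, 50])
        assert unmasked_length(drop_short_segments(c, min_len=50)) == 50


def test_masking_is_monotone():
    """No pipeline step ever unmasks a base."""
    rng = rng_stream(9, "monotone")
    seq = random_seq(rng, 800)
    seq = seq[:100] + seq[300:380] + seq[180:]  # create a duplicate block
    c = MaskedContig("c", seq, rng.random(len(seq)) < 0.1)
    before = c.mask.copy()
    (step1,) = apply_mask([c], [MaskInterval("c", 5, 25)])
    assert (step1.mask | ~before).all() or (before <= step1.mask).all()
    dup = find_duplicate_regions([step1], min_len=50)
    (step2,) = apply_mask([step1], dup)
    assert (step1.mask <= step2.mask).all()
    step3 = drop_short_segments(step2, min_len=50)
    assert (step2.mask <= step3.mask).all()


class TestIO:
    def test_fasta_softmask_round_trip(self, tmp_path):
        p = tmp_path / "ref.fasta"
        p.write_text(">c1\nACGTacgtNNNN\n>c2\nGGGGCCCC\n")
        contigs = read_fasta(p)
        assert contigs[0].mask.tolist() == [False] * 4 + [True] * 8
        assert contigs[0].seq == "ACGTACGTNNNN"
        contigs_nomask = read_fasta(p, honor_softmask=False)
        assert contigs_nomask[0].mask.tolist() == [False] * 8 + [True] * 4

    def test_hardmask_write(self, tmp_path):
        c = MaskedContig("c1", "ACGTACGT", np.array([0, 0, 1, 1, 0, 0, 0, 0], bool))
        write_fasta_hardmasked([c], tmp_path / "out.fasta")
        text = (tmp_path / "out.fasta").read_text()
        assert "ACNNACGT" in text

    def test_bed_round_trip(self, tmp_path):
        intervals = [MaskInterval("c1", 0, 10), MaskInterval("c2", 5, 9)]
        write_bed(intervals, tmp_path / "m.bed")
        assert read_bed(tmp_path / "m.bed") == intervals
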