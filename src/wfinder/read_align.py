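"""Read QC, unique-placement alignment, and the two per-contig features.

The mapper here is a deliberately minimal unique-placement aligner for short
fixed-length reads: a pigeonhole seed index guarantees that *every* placement
with at most ``max_mismatches`` substitutions (either strand, entirely within
unmasked sequence) is enumerated, after which a read is kept only if it has a
single strictly best placement genome-wide. This makes the mapper exactly
checkable against a brute-force Hamming scan. Indels, quality scores and
paired ends are out of scope; external aligners can be used instead through
:func:`ingest_sam`.

Features per contig (the classifier's inputs):

* coverage ``x1`` — fraction of unmasked bases covered by >= 1 read;
* read depth ``x2`` — number of placed reads divided by the number of
  positions where a read of length r fits entirely in unmasked sequence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from ._util import encode_seq, expand_ranges
from .reference_prep import MaskedContig, unmasked_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShortRead:
    id: str
    seq: str


@dataclass(frozen=True)
class ReadPlacement:
    """The unique best placement of one read on one contig."""

    read_id: str
    contig_id: str
    start: int
    mismatches: int
    strand: str = "+"


@dataclass(frozen=True)
class FeatureVector:
    contig_id: str
    x1: float  # coverage, fraction of unmasked bases hit
    x2: float  # read depth, reads / possible placements
    unmasked_len: int
    n_reads: int
    possible_placements: int
    eligible: bool


# ---------------------------------------------------------------------------
# read QC


def dedupe_reads(reads: list[ShortRead]) -> list[ShortRead]:
    """Keep one representative per distinct sequence, first occurrence order."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def filter_low_complexity(reads: list[ShortRead], max_mono_frac: float = 0.8) -> list[ShortRead]:
    """Drop reads whose most frequent base exceeds ``max_mono_frac`` of length."""
    if not 0 < max_mono_frac <= 1:
        raise ValueError("max_mono_frac must be in (0, 1]")
    out = []
    for r in reads:
        top = max(Counter(r.seq).values()) if r.seq else 0
        if top / max(len(r.seq), 1) <= max_mono_frac:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# unique-placement mapping


class GenomeIndex:
    """Pigeonhole seed index over the unmasked sequence of a reference.

    The read is partitioned into ``max_mismatches + 1`` contiguous segments;
    any placement with <= max_mismatches substitutions leaves at least one
    segment exact, so exact lookup of each segment's leading s-mer
    (s = r // (max_mismatches+1)) recovers every qualifying placement.
    """

    def __init__(self, contigs: list[MaskedContig], read_len: int, max_mismatches: int = 2):
        if read_len < 1:
            raise ValueError("read_len must be >= 1")
        self.contigs = contigs
        self.r = read_len
        self.max_mismatches = max_mismatches
        self.seed_len = read_len // (max_mismatches + 1)
        if self.seed_len < 1:
            raise ValueError("read too short for this mismatch budget")
        self.seed_offsets = [i * self.seed_len for i in range(max_mismatches + 1)]

        parts_codes, parts_invalid = [], []
        self.offsets = np.zeros(len(contigs), dtype=np.int64)
        pos = 0
        for i, c in enumerate(contigs):
            self.offsets[i] = pos
            codes = c.codes
            parts_codes.append(codes)
            parts_invalid.append(c.mask | (codes == 4))
            parts_codes.append(np.array([4], dtype=np.int8))
            parts_invalid.append(np.array([True]))
            pos += len(c) + 1
        self.codes = np.concatenate(parts_codes) if parts_codes else np.empty(0, np.int8)
        invalid = np.concatenate(parts_invalid) if parts_invalid else np.empty(0, bool)
        self.size = self.codes.size

        cs = np.concatenate([[0], np.cumsum(invalid.astype(np.int64))])
        r = self.r
        if self.size >= r:
            self.valid_start = (cs[r:] - cs[:-r]) == 0  # window fully unmasked
        else:
            self.valid_start = np.zeros(0, dtype=bool)
        self.n_windows = self.valid_start.size

        s = self.seed_len
        if self.size >= s:
            seed_ok = (cs[s:] - cs[:-s]) == 0
            scodes = np.zeros(self.size - s + 1, dtype=np.uint64)
            for j in range(s):
                scodes = scodes * np.uint64(4) + self.codes[j : j + scodes.size].astype(np.uint64)
            pos_valid = np.flatnonzero(seed_ok)
            codes_valid = scodes[pos_valid]
            order = np.argsort(codes_valid, kind="stable")
            self._seed_codes = codes_valid[order]
            self._seed_pos = pos_valid[order]
        else:
            self._seed_codes = np.empty(0, np.uint64)
            self._seed_pos = np.empty(0, np.int64)

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global positions to (contig index, local start)."""
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        return ci, gpos - self.offsets[ci]

    def _seed_candidates(self, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (read row, global window start) candidate pairs for one strand."""
        n = mat.shape[0]
        cand_rows, cand_pos = [], []
        s = self.seed_len
        for off in self.seed_offsets:
            codes = np.zeros(n, dtype=np.uint64)
            for j in range(s):
                codes = codes * np.uint64(4) + mat[:, off + j].astype(np.uint64)
            lo = np.searchsorted(self._seed_codes, codes, side="left")
            hi = np.searchsorted(self._seed_codes, codes, side="right")
            rows, flat = expand_ranges(lo, hi)
            gpos = self._seed_pos[flat] - off
            keep = (gpos >= 0) & (gpos < self.n_windows)
            rows, gpos = rows[keep], gpos[keep]
            keep = self.valid_start[gpos]
            cand_rows.append(rows[keep])
            cand_pos.append(gpos[keep])
        rows = np.concatenate(cand_rows) if cand_rows else np.empty(0, np.int64)
        gpos = np.concatenate(cand_pos) if cand_pos else np.empty(0, np.int64)
        if rows.size:
            key = rows * np.int64(self.size) + gpos
            _, first = np.unique(key, return_index=True)
            rows, gpos = rows[first], gpos[first]
        return rows, gpos

    def _verify(self, mat: np.ndarray, rows: np.ndarray, gpos: np.ndarray,
                chunk: int = 262144) -> np.ndarray:
        """Mismatch count of each candidate window against its read."""
        mm = np.empty(rows.size, dtype=np.int32)
        span = np.arange(self.r)
        for lo in range(0, rows.size, chunk):
            hi = min(lo + chunk, rows.size)
            windows = self.codes[gpos[lo:hi, None] + span]
            mm[lo:hi] = (windows != mat[rows[lo:hi]]).sum(axis=1)
        return mm


def map_reads_unique_detailed(
    reads: list[ShortRead],
    reference: list[MaskedContig],
    max_mismatches: int = 2,
    index: GenomeIndex | None = None,
) -> tuple[list[ReadPlacement], dict]:
    """Map reads to their strictly best unique placement; also return counts.

    A read is placed iff exactly one placement attains its minimum mismatch
    count (<= max_mismatches) over both strands and all fully-unmasked
    windows; ties and no-hit reads are discarded (tallied in the summary).
    """
    summary = {
        "n_reads_in": len(reads),
        "n_invalid": 0,
        "n_no_hit": 0,
        "n_ambiguous": 0,
        "n_placed": 0,
    }
    if not reads:
        return [], summary
    r = len(reads[0].seq)
    if any(len(rd.seq) != r for rd in reads):
        raise ValueError("all reads must have identical length")
    if index is None:
        index = GenomeIndex(reference, r, max_mismatches)
    elif index.r != r or index.max_mismatches < max_mismatches:
        raise ValueError("index was built with incompatible parameters")

    mat = np.stack([encode_seq(rd.seq) for rd in reads])
    ok = ~(mat == 4).any(axis=1)
    summary["n_invalid"] = int((~ok).sum())
    rows_all, pos_all, mm_all, strand_all = [], [], [], []
    for strand_code, smat in ((0, mat), (1, 3 - mat[:, ::-1])):  # + then revcomp
        rows, gpos = index._seed_candidates(np.where(smat == -1, 4, smat))
        valid_rows = ok[rows]
        rows, gpos = rows[valid_rows], gpos[valid_rows]
        if rows.size == 0:
            continue
        mm = index._verify(smat, rows, gpos)
        keep = mm <= max_mismatches
        rows_all.append(rows[keep])
        pos_all.append(gpos[keep])
        mm_all.append(mm[keep])
        strand_all.append(np.full(int(keep.sum()), strand_code, dtype=np.int8))

    if not rows_all or not sum(a.size for a in rows_all):
        summary["n_no_hit"] = int(ok.sum())
        return [], summary
    rows = np.concatenate(rows_all)
    gpos = np.concatenate(pos_all)
    mm = np.concatenate(mm_all)
    strand = np.concatenate(strand_all)

    order = np.lexsort((gpos, strand, mm, rows))
    rows, gpos, mm, strand = rows[order], gpos[order], mm[order], strand[order]
    first = np.concatenate([[True], rows[1:] != rows[:-1]])
    firsts = np.flatnonzero(first)
    nexts = np.concatenate([firsts[1:], [rows.size]])
    has_second = nexts - firsts >= 2
    second_mm = np.where(has_second, mm[np.minimum(firsts + 1, rows.size - 1)], np.iinfo(np.int32).max)
    unique = second_mm > mm[firsts]

    placed_idx = firsts[unique]
    n_hit_reads = firsts.size
    summary["n_ambiguous"] = int(n_hit_reads - placed_idx.size)
    summary["n_no_hit"] = int(ok.sum() - n_hit_reads)
    summary["n_placed"] = int(placed_idx.size)

    ci, local = index.locate(gpos[placed_idx])
    placements = [
        ReadPlacement(
            reads[int(rw)].id,
            reference[int(c)].id,
            int(p),
            int(m),
            "+" if s == 0 else "-",
        )
        for rw, c, p, m, s in zip(rows[placed_idx], ci, local, mm[placed_idx], strand[placed_idx])
    ]
    logger.info("mapping summary: %s", summary)
    return placements, summary


def map_reads_unique(
    reads: list[ShortRead],
    reference: list[MaskedContig],
    max_mismatches: int = 2,
    index: GenomeIndex | None = None,
) -> list[ReadPlacement]:
    placements, _ = map_reads_unique_detailed(reads, reference, max_mismatches, index)
    return placements


# ---------------------------------------------------------------------------
# SAM I/O


def _sam_header(reference: list[MaskedContig]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.id, "LN": len(c)} for c in reference],
    }


def write_sam(placements: list[ReadPlacement], reference: list[MaskedContig],
              path, read_seqs: dict[str, str] | None = None,
              read_len: int | None = None) -> None:
    """Write placements as plain-text SAM (flag 16 for reverse strand).

    A CIGAR is mandatory for mapped records, so either the read sequences or
    a uniform read length must be supplied.
    """
    tid = {c.id: i for i, c in enumerate(reference)}
    with pysam.AlignmentFile(str(path), "wh", header=_sam_header(reference)) as out:
        for p in placements:
            a = pysam.AlignedSegment(out.header)
            a.query_name = p.read_id
            a.flag = 16 if p.strand == "-" else 0
            a.reference_id = tid[p.contig_id]
            a.reference_start = p.start
            a.mapping_quality = 60
            seq = (read_seqs or {}).get(p.read_id)
            if seq is not None:
                a.query_sequence = seq
                a.cigarstring = f"{len(seq)}M"
            elif read_len is not None:
                a.cigarstring = f"{read_len}M"
            else:
                raise ValueError("write_sam needs read_seqs or read_len for CIGARs")
            a.set_tag("NM", p.mismatches)
            out.write(a)


def ingest_sam(path, reference: list[MaskedContig], min_mapping_quality: int = 1
               ) -> list[ReadPlacement]:
    """Turn primary mapped SAM records with MAPQ >= threshold into placements."""
    known = {c.id for c in reference}
    placements = []
    counts = Counter()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped:
                counts["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                counts["secondary_or_supplementary"] += 1
                continue
            if rec.mapping_quality < min_mapping_quality:
                counts["low_mapq"] += 1
                continue
            if rec.reference_name not in known:
                raise ValueError(
                    f"SAM record {i}: contig {rec.reference_name!r} absent from reference"
                )
            if rec.reference_start is None or rec.reference_start < 0:
                raise ValueError(f"malformed SAM record at body line {i}")
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            placements.append(
                ReadPlacement(
                    rec.query_name,
                    rec.reference_name,
                    int(rec.reference_start),
                    int(nm),
                    "-" if rec.is_reverse else "+",
                )
            )
            counts["primary_mapped"] += 1
    logger.info("SAM ingest: %s", dict(counts))
    return placements


# ---------------------------------------------------------------------------
# features


def possible_placements(contig: MaskedContig, r: int) -> int:
    """Number of start positions where a length-r read fits entirely unmasked."""
    if r < 1:
        raise ValueError("read length must be >= 1")
    return sum(max(0, (e - s) - r + 1) for s, e in contig.unmasked_segments())


def compute_features(contig: MaskedContig, placements: list[ReadPlacement], r: int
                     ) -> FeatureVector:
    """Coverage and read depth of one contig from its placements.

    A contig with no unmasked bases or no possible placement is flagged
    ineligible (its features are reported as 0 but must not be classified).
    """
    for p in placements:
        if p.contig_id != contig.id:
            raise ValueError(f"placement for {p.contig_id!r} passed to contig {contig.id!r}")
    ulen = unmasked_length(contig)
    pp = possible_placements(contig, r)
    if ulen == 0 or pp == 0:
        return FeatureVector(contig.id, 0.0, 0.0, ulen, len(placements), pp, False)
    covered = np.zeros(len(contig) + 1, dtype=np.int64)
    for p in placements:
        covered[p.start] += 1
        covered[min(p.start + r, len(contig))] -= 1
    hit = (np.cumsum(covered[:-1]) > 0) & ~contig.mask
    x1 = float(hit.sum() / ulen)
    x2 = float(len(placements) / pp)
    return FeatureVector(contig.id, x1, x2, ulen, len(placements), pp, True)


def features_frame(contigs: list[MaskedContig], placements: list[ReadPlacement], r: int
                   ) -> pd.DataFrame:
    """Per-contig feature table (one row per contig, labels included)."""
    by_contig: dict[str, list[ReadPlacement]] = {c.id: [] for c in contigs}
    for p in placements:
        by_contig[p.contig_id].append(p)
    rows = []
    for c in contigs:
        fv = compute_features(c, by_contig[c.id], r)
        rows.append(
            {
                "contig_id": fv.contig_id,
                "label": c.label,
                "unmasked_len": fv.unmasked_len,
                "n_reads": fv.n_reads,
                "possible_placements": fv.possible_placements,
                "x1": fv.x1,
                "x2": fv.x2,
                "eligible": fv.eligible,
            }
        )
    return pd.DataFrame(rows)


def write_features_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# FASTQ/FASTA read input


def read_short_reads(path) -> list[ShortRead]:
    """Load reads from FASTQ or FASTA (by extension)."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    from Bio import SeqIO

    return [ShortRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
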