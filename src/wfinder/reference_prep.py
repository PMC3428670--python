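"""Reference-assembly preparation: masking, duplicate filtering, segment cleanup.

The read-subtraction method depends on male reads mapping *uniquely*, so the
female assembly is first reduced to its unique, unmasked sequence:

1. external repeat/low-complexity masks are applied (BED intervals and/or
   lowercase soft masking in the FASTA);
2. exact duplicate regions longer than a minimum length — within or across
   contigs, on either strand — are masked so no read can have two perfect
   homes;
3. unmasked islands shorter than a minimum length are dropped, since they
   cannot anchor a read informatively.

Coordinates are 0-based half-open throughout; BED I/O follows BED
conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import bool_runs, encode_seq

logger = logging.getLogger(__name__)

# Closed label set: W-linked, autosomal/Z-linked ("non-W"), unanchored
# contigs awaiting classification, and unknown.
LABEL_W = "W"
LABEL_NONW = "NONW"
LABEL_UNMAPPED = "UNMAPPED"
LABEL_UNKNOWN = "UNKNOWN"
LABELS = frozenset({LABEL_W, LABEL_NONW, LABEL_UNMAPPED, LABEL_UNKNOWN})


@dataclass
class MaskedContig:
    """A named sequence with a per-base mask and an optional class label.

    ``mask[i] is True`` means base ``i`` is excluded from all downstream
    counting (repeat, duplicate, ambiguous, or N). Every non-ACGT base is
    forced into the mask on construction.
    """

    id: str
    seq: str
    mask: np.ndarray = None  # type: ignore[assignment]
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} for contig {self.id!r}")
        codes = encode_seq(self.seq)
        if self.mask is None:
            self.mask = np.zeros(len(self.seq), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
            if self.mask.shape != (len(self.seq),):
                raise ValueError(
                    f"mask length {self.mask.size} != sequence length "
                    f"{len(self.seq)} for contig {self.id!r}"
                )
        # invariant: every N (or other ambiguity code) is masked
        self.mask |= codes == 4

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        return encode_seq(self.seq)

    def unmasked_segments(self) -> list[tuple[int, int]]:
        """[start, end) intervals of maximal unmasked runs."""
        return bool_runs(~self.mask)


@dataclass(frozen=True)
class MaskInterval:
    """A BED-style [start, end) mask interval on one contig."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.contig_id!r}")


def apply_mask(contigs: list[MaskedContig], intervals: list[MaskInterval]) -> list[MaskedContig]:
    """Mask every base inside any interval; existing masks are preserved (union)."""
    by_id = {c.id: c for c in contigs}
    new_masks = {c.id: c.mask.copy() for c in contigs}
    for iv in intervals:
        if iv.contig_id not in by_id:
            raise KeyError(f"mask interval references unknown contig {iv.contig_id!r}")
        n = len(by_id[iv.contig_id])
        if iv.end > n:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) out of bounds for contig "
                f"{iv.contig_id!r} of length {n}"
            )
        new_masks[iv.contig_id][iv.start : iv.end] = True
    return [replace(c, mask=new_masks[c.id]) for c in contigs]


_HASH_BASE = 1099511628211  # odd 64-bit multiplier for the rolling hash
_U64 = np.uint64(_HASH_BASE)


def _forward_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Polynomial hash (mod 2^64) of every length-k window, MSB-first."""
    n = codes.size - k + 1
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = h * _U64 + codes[j : j + n].astype(np.uint64)
    return h


def _revcomp_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Hash of the reverse complement of every length-k window.

    rc(s)[j] = comp(s[k-1-j]), so hash(rc(s)) = sum_i comp(s[i]) * B^i.
    """
    n = codes.size - k + 1
    comp = (3 - codes).astype(np.uint64)  # A<->T, C<->G on 2-bit codes
    h = np.zeros(n, dtype=np.uint64)
    power = 1
    for j in range(k):
        h = h + comp[j : j + n] * np.uint64(power)
        power = (power * _HASH_BASE) & 0xFFFFFFFFFFFFFFFF
    return h


def find_duplicate_regions(
    contigs: list[MaskedContig], min_len: int = 50
) -> list[MaskInterval]:
    """Locate every base inside an exact repeat longer than ``min_len``.

    A position is reported when it lies in a maximal exact match of length
    > min_len present at >= 2 distinct genomic locations, counting both the
    forward strand and the reverse complement, within or across contigs, and
    considering unmasked sequence only. All copies are reported. Equivalent
    formulation used here: a base is duplicated iff it sits inside some
    (min_len+1)-mer window whose sequence (or reverse complement) occurs at
    another location.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    k = min_len + 1
    if not contigs:
        return []

    # Concatenate contigs with a masked sentinel base between them so no
    # window spans a boundary.
    parts_codes, parts_masked = [], []
    offsets, order = [], []
    pos = 0
    for c in contigs:
        offsets.append(pos)
        order.append(c.id)
        parts_codes.append(c.codes)
        parts_masked.append(c.mask | (c.codes == 4))
        parts_codes.append(np.array([4], dtype=np.int8))
        parts_masked.append(np.array([True]))
        pos += len(c) + 1
    codes = np.concatenate(parts_codes)
    invalid = np.concatenate(parts_masked)
    if codes.size < k:
        return []

    # window is usable iff it contains no masked base
    cs = np.concatenate([[0], np.cumsum(invalid.astype(np.int64))])
    valid = (cs[k:] - cs[:-k]) == 0
    starts = np.flatnonzero(valid)
    if starts.size == 0:
        return []

    hf = _forward_hashes(codes, k)[starts]
    hr = _revcomp_hashes(codes, k)[starts]
    uniq, counts = np.unique(hf, return_counts=True)
    cf = counts[np.searchsorted(uniq, hf)]
    idx = np.searchsorted(uniq, hr)
    idx_clipped = np.minimum(idx, uniq.size - 1)
    rc_present = (uniq[idx_clipped] == hr) & (idx < uniq.size)
    cr = np.where(rc_present, counts[idx_clipped], 0)
    # palindromic windows (hr == hf) only duplicate via a second location
    dup = (cf >= 2) | ((hr != hf) & (cr >= 1))

    dup_starts = starts[dup]
    covered = np.zeros(codes.size + 1, dtype=np.int64)
    np.add.at(covered, dup_starts, 1)
    np.add.at(covered, dup_starts + k, -1)
    dup_base = np.cumsum(covered[:-1]) > 0

    intervals: list[MaskInterval] = []
    for cid, off, c in zip(order, offsets, contigs):
        for s, e in bool_runs(dup_base[off : off + len(c)]):
            intervals.append(MaskInterval(cid, int(s), int(e)))
    return intervals


def drop_short_segments(contig: MaskedContig, min_len: int = 50) -> MaskedContig:
    """Mask every maximal unmasked run shorter than ``min_len`` bases.

    Idempotent: surviving runs are >= min_len and are left untouched.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    mask = contig.mask.copy()
    for s, e in contig.unmasked_segments():
        if e - s < min_len:
            mask[s:e] = True
    return replace(contig, mask=mask)


def unmasked_length(contig: MaskedContig) -> int:
    """Number of unmasked bases."""
    return int((~contig.mask).sum())


def prep_reference(
    contigs: list[MaskedContig],
    mask_intervals: list[MaskInterval] | None = None,
    min_dup_len: int = 50,
    min_seg_len: int = 50,
) -> tuple[list[MaskedContig], dict]:
    """Run the full filter chain and return (prepped contigs, funnel counts)."""
    funnel = {
        "n_contigs_in": len(contigs),
        "unmasked_bp_in": sum(unmasked_length(c) for c in contigs),
    }
    if mask_intervals:
        contigs = apply_mask(contigs, mask_intervals)
    funnel["unmasked_bp_after_external_mask"] = sum(unmasked_length(c) for c in contigs)
    dup = find_duplicate_regions(contigs, min_len=min_dup_len)
    contigs = apply_mask(contigs, dup)
    funnel["n_duplicate_intervals"] = len(dup)
    funnel["unmasked_bp_after_dup_mask"] = sum(unmasked_length(c) for c in contigs)
    contigs = [drop_short_segments(c, min_len=min_seg_len) for c in contigs]
    funnel["unmasked_bp_after_short_drop"] = sum(unmasked_length(c) for c in contigs)
    funnel["n_contigs_with_sequence"] = sum(1 for c in contigs if unmasked_length(c) > 0)
    logger.info("reference prep funnel: %s", funnel)
    return contigs, funnel


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path, honor_softmask: bool = True, labels: dict[str, str] | None = None
               ) -> list[MaskedContig]:
    """Load a FASTA assembly; lowercase bases become masked unless disabled."""
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        mask = None
        if honor_softmask:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            mask = (arr >= 97) & (arr <= 122)
        label = (labels or {}).get(rec.id, LABEL_UNKNOWN)
        contigs.append(MaskedContig(rec.id, seq.upper(), mask, label))
    return contigs


def write_fasta_hardmasked(contigs: list[MaskedContig], path) -> None:
    """Write the assembly with masked bases replaced by N."""
    records = []
    for c in contigs:
        arr = np.frombuffer(c.seq.upper().encode("ascii"), dtype=np.uint8).copy()
        arr[c.mask] = ord("N")
        records.append(SeqRecord(Seq(arr.tobytes().decode("ascii")), id=c.id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> list[MaskInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cid, start, end = line.split("\t")[:3]
            intervals.append(MaskInterval(cid, int(start), int(end)))
    return intervals


def write_bed(intervals: list[MaskInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\n")


def write_mask_bed(contigs: list[MaskedContig], path) -> None:
    """Write the current mask state of every contig as BED."""
    intervals = [
        MaskInterval(c.id, s, e) for c in contigs for s, e in bool_runs(c.mask)
    ]
    write_bed(intervals, path)


def write_lengths_tsv(contigs: list[MaskedContig], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\tunmasked_length\tlabel\n")
        for c in contigs:
            fh.write(f"{c.id}\t{len(c)}\t{unmasked_length(c)}\t{c.label}\n")


def read_labels_tsv(path) -> dict[str, str]:
    """Read a two-column (contig_id, label) TSV, header optional."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("", "contig_id"):
                continue
            if parts[1] not in LABELS:
                raise ValueError(f"unknown label {parts[1]!r} for contig {parts[0]!r}")
            labels[parts[0]] = parts[1]
    return labels
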