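"""Shared low-level helpers: sequence encoding, seeded RNG streams, ranges."""

from __future__ import annotations

import zlib

import numpy as np

# Byte -> 2-bit base code; anything outside ACGT/acgt (incl. N) maps to 4.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_BASES = "ACGTN"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from (master seed, label).

    The label is folded in through CRC32 so that every operation in a run
    draws from its own substream of one master seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-row [lo, hi) index ranges into (row_index, flat_index) arrays."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rows = np.repeat(np.arange(lo.size, dtype=np.int64), counts)
    starts = np.repeat(lo.astype(np.int64), counts)
    offsets = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(counts) - counts, counts)
    return rows, starts + offsets


def bool_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Return [start, end) intervals of the True runs of a boolean vector."""
    v = np.asarray(values, dtype=bool)
    if v.size == 0:
        return []
    padded = np.concatenate([[False], v, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def mark_intervals(length: int, intervals) -> np.ndarray:
    """Boolean vector with True inside any of the given [start, end) intervals."""
    delta = np.zeros(length + 1, dtype=np.int64)
    for start, end in intervals:
        delta[start] += 1
        delta[end] -= 1
    return np.cumsum(delta[:-1]) > 0
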