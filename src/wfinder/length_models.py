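"""Length-conditioned training material.

Short contigs receive few reads regardless of class, so the classifier
conditions on contig length: contigs are assigned to 500-bp length bins, and
per-bin training sets are produced by fragmenting the labeled (mapped)
portion of the reference into fixed-length windows. Placements are carried
over to fragments by windowing (a read belongs to the fragment containing
its start; reads spanning a fragment boundary are dropped and counted),
which is deterministic and avoids re-running alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import rng_stream
from .read_align import ReadPlacement, features_frame
from .reference_prep import MaskedContig

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 500

FRAGMENT_SEP = "|"  # fragment ids are "<source id>|<window start>"


def length_bin(raw_len: int, width: int = DEFAULT_BIN_WIDTH) -> int:
    """Round a length to the nearest multiple of ``width``.

    Ties (x == width/2 mod width) round up; the result is floored at the
    smallest bin, ``width``.
    """
    if raw_len < 1:
        raise ValueError("length must be >= 1")
    k = (raw_len + width // 2) // width
    return int(max(1, k) * width)


def fragment_genome(contigs: list[MaskedContig], L: int) -> list[MaskedContig]:
    """Cut each contig into consecutive non-overlapping windows of exactly L bases.

    Windows start at position 0; the trailing partial window is discarded.
    Mask state and label are inherited.
    """
    if L < 1:
        raise ValueError("fragment length must be >= 1")
    fragments = []
    for c in contigs:
        for w in range(len(c) // L):
            s = w * L
            fragments.append(
                MaskedContig(
                    f"{c.id}{FRAGMENT_SEP}{s}",
                    c.seq[s : s + L],
                    c.mask[s : s + L],
                    c.label,
                )
            )
    return fragments


def assign_placements_to_fragments(
    contigs: list[MaskedContig], placements: list[ReadPlacement], L: int, r: int
) -> tuple[list[ReadPlacement], int]:
    """Re-home placements onto L-length fragments of their source contigs.

    A placement is kept iff the whole read [start, start+r) falls inside one
    complete fragment window; the number of dropped (boundary-spanning or
    tail-window) placements is returned alongside.
    """
    n_windows = {c.id: len(c) // L for c in contigs}
    out = []
    lost = 0
    for p in placements:
        w = p.start // L
        if w < n_windows.get(p.contig_id, 0) and p.start + r <= (w + 1) * L:
            out.append(replace(p, contig_id=f"{p.contig_id}{FRAGMENT_SEP}{w * L}",
                               start=p.start - w * L))
        else:
            lost += 1
    return out, lost


def fragment_features(
    contigs: list[MaskedContig], placements: list[ReadPlacement], L: int, r: int
) -> pd.DataFrame:
    """Feature table of the L-fragmented genome using re-homed placements."""
    fragments = fragment_genome(contigs, L)
    frag_placements, lost = assign_placements_to_fragments(contigs, placements, L, r)
    logger.info("fragmentation at L=%d: %d fragments, %d boundary reads lost",
                L, len(fragments), lost)
    return features_frame(fragments, frag_placements, r)


@dataclass
class TrainingSet:
    """Labeled feature vectors for one length bin, at a chosen class ratio."""

    L: int
    members: pd.DataFrame  # columns: contig_id, label, x1, x2, unmasked_len
    ratio: float

    def __post_init__(self) -> None:
        if self.members.empty:
            raise ValueError("training set must not be empty")


def build_training_set(
    features: pd.DataFrame,
    L: int,
    n_w: int,
    ratio_nonw_to_w: float,
    seed: int,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> TrainingSet:
    """Draw a per-bin training set of n_w W and round(ratio * n_w) non-W contigs.

    Drawing is uniform without replacement and reproducible from the seed.
    """
    bins = features["unmasked_len"].map(lambda v: length_bin(int(v), bin_width))
    pool = features[bins == L]
    w_pool = pool[pool["label"] == "W"]
    nonw_pool = pool[pool["label"] == "NONW"]
    n_nonw = int(round(ratio_nonw_to_w * n_w))
    if len(w_pool) < n_w or len(nonw_pool) < n_nonw:
        raise ValueError(
            f"insufficient members at L={L}: need {n_w} W / {n_nonw} non-W, "
            f"have {len(w_pool)} W / {len(nonw_pool)} non-W"
        )
    rng = rng_stream(seed, f"training-set-L{L}")
    w_idx = rng.choice(len(w_pool), size=n_w, replace=False)
    nonw_idx = rng.choice(len(nonw_pool), size=n_nonw, replace=False)
    members = pd.concat([w_pool.iloc[np.sort(w_idx)], nonw_pool.iloc[np.sort(nonw_idx)]],
                        ignore_index=True)
    return TrainingSet(L, members, ratio_nonw_to_w)


def write_training_set_tsv(ts: TrainingSet, path) -> None:
    df = ts.members.copy()
    df.insert(1, "L", ts.L)
    df.to_csv(path, sep="\t", index=False)
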