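"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the production code paths: duplicates are found by
an exact substring dictionary, mapping by a full sliding-window Hamming
scan, and AUC by exhaustive pairwise concordance.
"""

from __future__ import annotations

import numpy as np

from wfinder._util import encode_seq, revcomp


def brute_duplicate_mask(contigs, min_len: int) -> dict[str, np.ndarray]:
    """Per-contig boolean mask of bases inside repeats longer than min_len.

    Exact substring-dictionary scan over (min_len+1)-mers of unmasked
    sequence, forward and reverse complement, marking every copy.
    """
    k = min_len + 1
    occurrences: dict[str, list[tuple[str, int]]] = {}
    windows: dict[str, list[tuple[int, str]]] = {c.id: [] for c in contigs}
    for c in contigs:
        for start in range(len(c) - k + 1):
            if c.mask[start : start + k].any():
                continue
            s = c.seq[start : start + k]
            occurrences.setdefault(s, []).append((c.id, start))
            windows[c.id].append((start, s))
    out = {c.id: np.zeros(len(c), dtype=bool) for c in contigs}
    for c in contigs:
        for start, s in windows[c.id]:
            rc = revcomp(s)
            dup = len(occurrences.get(s, [])) >= 2 or (
                rc != s and len(occurrences.get(rc, [])) >= 1
            )
            if dup:
                out[c.id][start : start + k] = True
    return out


def brute_force_unique_map(reads, contigs, max_mismatches: int):
    """Sliding-window Hamming scan returning per-read placement decisions.

    Returns {read_id: (contig_id, start, strand, mismatches)} for uniquely
    placed reads, {read_id: None} for ambiguous ones; no-hit reads absent.
    """
    results = {}
    for read in reads:
        rm = encode_seq(read.seq)
        if (rm == 4).any():
            continue
        r = rm.size
        hits = []
        for c in contigs:
            codes = c.codes
            invalid = c.mask | (codes == 4)
            n = len(c) - r + 1
            if n <= 0:
                continue
            cs = np.concatenate([[0], np.cumsum(invalid)])
            valid = (cs[r:] - cs[:-r]) == 0
            for strand, rr in (("+", rm), ("-", (3 - rm[::-1]) % 4)):
                mm = np.zeros(n, dtype=np.int64)
                for j in range(r):
                    mm += codes[j : j + n] != rr[j]
                for pos in np.flatnonzero(valid & (mm <= max_mismatches)):
                    hits.append((int(mm[pos]), c.id, int(pos), strand))
        if not hits:
            continue
        best = min(h[0] for h in hits)
        best_hits = [h for h in hits if h[0] == best]
        if len(best_hits) == 1:
            mmc, cid, pos, strand = best_hits[0]
            results[read.id] = (cid, pos, strand, mmc)
        else:
            results[read.id] = None
    return results


def pairwise_auc(scores, labels) -> float:
    """Exhaustive Mann-Whitney pairwise concordance with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos = s[y]
    neg = s[~y]
    wins = 0.0
    for p in pos:
        wins += float((p > neg).sum()) + 0.5 * float((p == neg).sum())
    return wins / (pos.size * neg.size)


def per_base_features(contig, placements, r: int) -> tuple[float, float]:
    """Per-base counting oracle for (coverage, read depth)."""
    hit = np.zeros(len(contig), dtype=bool)
    for p in placements:
        hit[p.start : p.start + r] = True
    unmasked = ~contig.mask
    ulen = int(unmasked.sum())
    possible = 0
    for start in range(len(contig) - r + 1):
        if not contig.mask[start : start + r].any():
            possible += 1
    x1 = float((hit & unmasked).sum() / ulen) if ulen else 0.0
    x2 = float(len(placements) / possible) if possible else 0.0
    return x1, x2
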