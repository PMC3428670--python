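"""Synthetic ZW assemblies and ZZ read sets with known truth.

The generator emulates the data regime the subtraction method was designed
for: a female (ZW) assembly containing W-specific, Z-linked and autosomal
contigs, and a male (ZZ) short-read set drawn only from non-W sequence.
Because ZZ males carry two Z chromosomes, Z contigs are sampled at the same
per-copy rate as autosomes — Z is deliberately *not* depth-distinguishable
from autosomes, matching the two-class (W vs non-W) design.

Base composition is uniform and read starts are sampled uniformly over
eligible windows (no GC or fragmentation bias); sequencing errors are
uniform substitutions. Two realistic failure modes can be planted:

* gametolog pairs — a W contig carries a stretch identical to the male's
  copy of a recent W/Z duplication, while the assembly's Z partner carries a
  diverged copy; male reads from that region then best-map uniquely to the
  W contig, so the W contig picks up coverage it "should not" have;
* male-deletion contigs — present in the female assembly, labeled non-W,
  but absent from the male read source; they look exactly like W contigs
  and are the method's unavoidable false positives.

Everything is reproducible from the spec's master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import decode_codes, encode_seq, rng_stream
from .read_align import ShortRead, map_reads_unique_detailed, possible_placements, write_sam
from .reference_prep import (
    LABEL_NONW,
    LABEL_W,
    MaskedContig,
    unmasked_length,
    write_fasta_hardmasked,
    write_mask_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class GenomeSpec:
    """Study conditions for one synthetic experiment.

    Defaults model a desk-scale version of a low-coverage avian survey:
    36-bp reads at 0.45x depth of the unmasked assembly, ~1:10 W:non-W
    contig ratio, contigs of 1-5 kb (the hard, short end of an assembly),
    a small planted fraction of exact repeats, and a low substitution error
    rate typical of filtered short-read data. Gametologs and male deletions
    default to zero: the baseline models a vetted labeled set; both failure
    modes are opt-in.
    """

    n_w: int = 100
    n_z: int = 100
    n_autosome: int = 900
    w_len_range: tuple[int, int] = (1000, 5000)
    z_len_range: tuple[int, int] = (1000, 5000)
    autosome_len_range: tuple[int, int] = (1000, 5000)
    read_len: int = 36
    depth: float = 0.45
    error_rate: float = 0.002
    repeat_fraction: float = 0.02
    repeat_unit_lengths: tuple[int, ...] = (150, 400)
    n_gametolog_pairs: int = 0
    gametolog_len: int = 300
    gametolog_divergence: float = 0.03
    n_male_deletions: int = 0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if min(self.n_w, self.n_z, self.n_autosome) < 0:
            raise ValueError("contig counts must be >= 0")
        for lo, hi in (self.w_len_range, self.z_len_range, self.autosome_len_range):
            if lo < self.read_len:
                raise ValueError("contig lengths must be >= read length")
            if hi < lo:
                raise ValueError("length range must satisfy lo <= hi")
        if not 0 <= self.error_rate <= 1 or not 0 <= self.repeat_fraction <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.n_gametolog_pairs > min(self.n_w, self.n_z):
            raise ValueError("more gametolog pairs than W or Z contigs")
        if self.n_male_deletions > self.n_autosome:
            raise ValueError("more male deletions than autosomal contigs")


@dataclass
class TruthTable:
    """Ground-truth per-contig annotations for parameter recovery testing."""

    frame: pd.DataFrame  # index: contig_id; columns below
    # male-genome sequence differing from the assembly (gametolog Z partners)
    read_source_overrides: dict[str, str] = field(default_factory=dict)

    def label(self, contig_id: str) -> str:
        return self.frame.loc[contig_id, "label"]


def _mutate(seq: str, rate_or_n, rng: np.random.Generator) -> str:
    codes = encode_seq(seq).copy()
    if isinstance(rate_or_n, float):
        sites = np.flatnonzero(rng.random(codes.size) < rate_or_n)
    else:
        sites = rng.choice(codes.size, size=min(rate_or_n, codes.size), replace=False)
    codes[sites] = (codes[sites] + rng.integers(1, 4, size=sites.size)) % 4
    return decode_codes(codes)


def simulate_genome(spec: GenomeSpec) -> tuple[list[MaskedContig], TruthTable]:
    """Generate the labeled female assembly and its truth table."""
    rng = rng_stream(spec.seed, "genome")

    classes = (
        [("W", LABEL_W, spec.w_len_range)] * spec.n_w
        + [("Z", LABEL_NONW, spec.z_len_range)] * spec.n_z
        + [("AUT", LABEL_NONW, spec.autosome_len_range)] * spec.n_autosome
    )
    contigs: list[MaskedContig] = []
    rows = []
    seqs: dict[str, np.ndarray] = {}
    for i, (chrom_class, label, (lo, hi)) in enumerate(classes):
        n = int(rng.integers(lo, hi + 1))
        codes = rng.integers(0, 4, size=n).astype(np.int8)
        cid = f"{chrom_class.lower()}_{i:05d}"
        seqs[cid] = codes
        rows.append({"contig_id": cid, "label": label, "chrom_class": chrom_class,
                     "is_gametolog": False, "is_male_deleted": False, "repeat_bases": 0})
    truth = pd.DataFrame(rows).set_index("contig_id")

    # reserved intervals per contig (gametolog stretches must stay clean)
    reserved: dict[str, list[tuple[int, int]]] = {cid: [] for cid in truth.index}
    overrides: dict[str, str] = {}

    # gametolog pairs: W carries the male's copy; the assembly Z partner a
    # diverged one; male reads for the partner are generated from the
    # W-identical variant (see module docstring).
    grng = rng_stream(spec.seed, "gametologs")
    w_ids = [cid for cid in truth.index if truth.loc[cid, "chrom_class"] == "W"]
    z_ids = [cid for cid in truth.index if truth.loc[cid, "chrom_class"] == "Z"]
    for k in range(spec.n_gametolog_pairs):
        w_id, z_id = w_ids[k], z_ids[k]
        glen = spec.gametolog_len
        if glen > min(seqs[w_id].size, seqs[z_id].size):
            raise ValueError("gametolog stretch longer than contig")
        stretch = grng.integers(0, 4, size=glen).astype(np.int8)
        pw = int(grng.integers(0, seqs[w_id].size - glen + 1))
        pz = int(grng.integers(0, seqs[z_id].size - glen + 1))
        seqs[w_id][pw : pw + glen] = stretch
        diverged = encode_seq(_mutate(decode_codes(stretch), spec.gametolog_divergence, grng))
        seqs[z_id][pz : pz + glen] = diverged
        male_copy = seqs[z_id].copy()
        male_copy[pz : pz + glen] = stretch
        overrides[z_id] = decode_codes(male_copy)
        reserved[w_id].append((pw, pw + glen))
        reserved[z_id].append((pz, pz + glen))
        truth.loc[w_id, "is_gametolog"] = True
        truth.loc[z_id, "is_gametolog"] = True

    # planted exact repeats (multi-copy units, any class, both detectable by
    # the duplicate finder and realistic contamination for the mapper)
    rrng = rng_stream(spec.seed, "repeats")
    total_len = sum(s.size for s in seqs.values())
    target = spec.repeat_fraction * total_len
    planted = 0
    ids = list(truth.index)
    lengths = np.array([seqs[cid].size for cid in ids])
    guard = 0
    while planted < target and guard < 10000:
        guard += 1
        unit_len = int(rrng.choice(spec.repeat_unit_lengths))
        if unit_len > lengths.max():
            raise ValueError("repeat unit longer than every contig")
        copies = int(rrng.integers(2, 5))
        unit = rrng.integers(0, 4, size=unit_len).astype(np.int8)
        placed = 0
        for _ in range(copies):
            for _attempt in range(20):
                ci = int(rrng.integers(0, len(ids)))
                cid = ids[ci]
                if seqs[cid].size < unit_len:
                    continue
                pos = int(rrng.integers(0, seqs[cid].size - unit_len + 1))
                if any(pos < e and s < pos + unit_len for s, e in reserved[cid]):
                    continue
                seqs[cid][pos : pos + unit_len] = unit
                truth.loc[cid, "repeat_bases"] += unit_len
                placed += 1
                break
        planted += placed * unit_len

    # male-specific deletions: autosomal contigs absent from the read source
    drng = rng_stream(spec.seed, "deletions")
    aut_ids = [cid for cid in truth.index if truth.loc[cid, "chrom_class"] == "AUT"]
    for cid in drng.choice(aut_ids, size=spec.n_male_deletions, replace=False):
        truth.loc[cid, "is_male_deleted"] = True

    for cid in truth.index:
        contigs.append(MaskedContig(cid, decode_codes(seqs[cid]), None, truth.loc[cid, "label"]))
    logger.info("simulated genome: %d contigs, %d bp, %d bp planted repeats",
                len(contigs), total_len, int(planted))
    return contigs, TruthTable(truth, overrides)


def simulate_male_reads_detailed(
    genome: list[MaskedContig], truth: TruthTable, spec: GenomeSpec
) -> tuple[list[ShortRead], pd.DataFrame]:
    """Male (ZZ) reads plus a provenance table (source contig and start).

    Read starts are uniform over all read-length windows of non-W,
    non-deleted contigs; the total count is depth x unmasked assembly
    length / read length; substitution errors are applied at the spec rate.
    """
    r = spec.read_len
    sources = []
    for c in genome:
        row = truth.frame.loc[c.id]
        if row["label"] == LABEL_W or row["is_male_deleted"]:
            continue
        seq = truth.read_source_overrides.get(c.id, c.seq)
        if len(seq) >= r:
            sources.append((c.id, encode_seq(seq)))
    if not sources:
        raise ValueError("no eligible read-source sequence (all W or deleted)")

    windows = np.array([s.size - r + 1 for _, s in sources], dtype=np.int64)
    unmasked_total = sum(unmasked_length(c) for c in genome)
    n_reads = int(round(spec.depth * unmasked_total / r))

    rng = rng_stream(spec.seed, "reads")
    counts = rng.multinomial(n_reads, windows / windows.sum())
    read_rows = []
    mats = []
    prov_contig, prov_start = [], []
    for (cid, codes), cnt in zip(sources, counts):
        if cnt == 0:
            continue
        starts = rng.integers(0, codes.size - r + 1, size=cnt)
        mats.append(codes[starts[:, None] + np.arange(r)])
        prov_contig.extend([cid] * int(cnt))
        prov_start.extend(starts.tolist())
    mat = np.concatenate(mats) if mats else np.empty((0, r), np.int8)

    if spec.error_rate > 0 and mat.size:
        err = rng.random(mat.shape) < spec.error_rate
        shift = rng.integers(1, 4, size=mat.shape)
        mat = np.where(err, (mat + shift) % 4, mat).astype(np.int8)

    reads = [ShortRead(f"read{i:08d}", decode_codes(row)) for i, row in enumerate(mat)]
    prov = pd.DataFrame({"read_id": [rd.id for rd in reads],
                         "source_contig": prov_contig, "source_start": prov_start})
    logger.info("simulated %d male reads (%.3gx of %d unmasked bp)",
                len(reads), spec.depth, unmasked_total)
    return reads, prov


def simulate_male_reads(genome: list[MaskedContig], truth: TruthTable,
                        spec: GenomeSpec) -> list[ShortRead]:
    reads, _ = simulate_male_reads_detailed(genome, truth, spec)
    return reads


def expected_zero_hit_probability(contig: MaskedContig, n_reads: int,
                                  total_placements: int, r: int) -> float:
    """Closed-form P(contig receives zero reads) under uniform placement.

    With ``p`` possible placements on the contig out of ``total_placements``
    genome-wide and n_reads placed independently, the zero-hit probability
    is (1 - p/total)^n.
    """
    p = possible_placements(contig, r)
    if p == 0:
        raise ValueError(f"contig {contig.id!r} has no possible placement")
    if total_placements < p:
        raise ValueError("total_placements must be >= the contig's own placements")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    return float((1 - p / total_placements) ** n_reads)


def write_fixture(genome: list[MaskedContig], truth: TruthTable,
                  reads: list[ShortRead], out_dir, spec: GenomeSpec,
                  sam: bool = False) -> dict:
    """Write the fixture file set; returns the manifest (also saved as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta_hardmasked(genome, out / "reference.fasta")
    write_mask_bed(genome, out / "mask.bed")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("contig_id\tlabel\n")
        for c in genome:
            fh.write(f"{c.id}\t{c.label}\n")
    truth.frame.to_csv(out / "truth.tsv", sep="\t")
    with open(out / "reads.fastq", "w") as fh:
        for rd in reads:
            fh.write(f"@{rd.id}\n{rd.seq}\n+\n{'I' * len(rd.seq)}\n")
    manifest = {
        "spec": dataclasses.asdict(spec),
        "seed": spec.seed,
        "n_contigs": len(genome),
        "n_reads": len(reads),
        "files": ["reference.fasta", "mask.bed", "labels.tsv", "truth.tsv", "reads.fastq"],
    }
    if sam:
        placements, summary = map_reads_unique_detailed(reads, genome)
        write_sam(placements, genome, out / "placements.sam",
                  {rd.id: rd.seq for rd in reads})
        manifest["files"].append("placements.sam")
        manifest["mapping_summary"] = summary
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
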