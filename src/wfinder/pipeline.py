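"""Run configuration and end-to-end pipeline orchestration.

The pipeline ties the stages together in the order the method prescribes:
prep (mask + duplicate filter + short-segment drop) -> read QC + unique
mapping -> per-contig features -> separation statistics on the labeled
contigs -> classifier training on the labeled contigs -> classification of
the unanchored contigs. Every run resolves its configuration up front,
writes a frozen copy next to the outputs, stamps the manifest with the
config hash, and logs a funnel of counts at each filtering stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import bayes_classifier, read_align, reference_prep, separation_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a run; defaults follow the method's standard settings."""

    read_len: int = 36
    max_mismatches: int = 2
    min_dup_len: int = 50
    min_seg_len: int = 50
    max_mono_frac: float = 0.8
    min_mapping_quality: int = 1
    bin_width: float = 0.005
    epsilon: float = 1e-6
    prior_w: float | None = None
    mode: str = "standard_bayes"
    tau: float = 0.95
    B: int = 1000
    ci_level: float = 0.95
    iterations: int = 100
    honor_softmask: bool = True
    seed: int = 17

    def __post_init__(self) -> None:
        if self.read_len < 1 or self.max_mismatches < 0:
            raise ValueError("invalid read/mismatch configuration")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if self.B < 1 or self.iterations < 1:
            raise ValueError("B and iterations must be >= 1")
        if self.mode not in bayes_classifier.MODES:
            raise ValueError(f"mode must be one of {bayes_classifier.MODES}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update(overrides)
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    reference_fasta,
    out_dir,
    reads_path=None,
    sam_path=None,
    mask_bed=None,
    labels_tsv=None,
) -> dict:
    """Execute prep -> features -> stats -> train -> classify; return the manifest.

    Contigs labeled W/NONW (via the labels TSV) are the known training set;
    contigs labeled UNMAPPED (or unlabeled) are classified. Reads come from
    a FASTQ/FASTA, or precomputed alignments from a SAM.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "config_hash": config.config_hash(),
                      "stages": {}, "complete": False}
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, sort_keys=True, indent=1)

    def stage(name, fn):
        try:
            logger.info("stage %s ...", name)
            result = fn()
            manifest["stages"][name] = "ok"
            return result
        except Exception as exc:  # noqa: BLE001 - stage boundary
            manifest["stages"][name] = f"failed: {exc}"
            _write_manifest(manifest, out)
            raise StageError(name, exc) from exc

    def _prep():
        labels = reference_prep.read_labels_tsv(labels_tsv) if labels_tsv else {}
        contigs = reference_prep.read_fasta(reference_fasta,
                                            honor_softmask=config.honor_softmask,
                                            labels=labels)
        intervals = reference_prep.read_bed(mask_bed) if mask_bed else None
        prepped, funnel = reference_prep.prep_reference(
            contigs, intervals, config.min_dup_len, config.min_seg_len)
        reference_prep.write_fasta_hardmasked(prepped, out / "reference.prepped.fasta")
        reference_prep.write_mask_bed(prepped, out / "mask.prepped.bed")
        reference_prep.write_lengths_tsv(prepped, out / "contig_lengths.tsv")
        manifest["funnel"] = funnel
        return prepped

    contigs = stage("prep", _prep)

    def _align():
        if sam_path:
            placements = read_align.ingest_sam(sam_path, contigs,
                                               config.min_mapping_quality)
            summary = {"source": "sam", "n_placed": len(placements)}
        elif reads_path:
            reads = read_align.read_short_reads(reads_path)
            n0 = len(reads)
            reads = read_align.dedupe_reads(reads)
            n1 = len(reads)
            reads = read_align.filter_low_complexity(reads, config.max_mono_frac)
            n2 = len(reads)
            placements, summary = read_align.map_reads_unique_detailed(
                reads, contigs, config.max_mismatches)
            summary = {"source": "fastq", "n_raw": n0, "n_after_dedupe": n1,
                       "n_after_complexity": n2, **summary}
        else:
            raise ValueError("either reads_path or sam_path is required")
        manifest["alignment"] = summary
        return placements

    placements = stage("align", _align)

    def _features():
        df = read_align.features_frame(contigs, placements, config.read_len)
        read_align.write_features_tsv(df, out / "features.tsv")
        return df

    features = stage("features", _features)

    labeled = features[features["label"].isin(["W", "NONW"])]
    to_classify = features[~features["label"].isin(["W", "NONW"])]
    manifest["counts"] = {
        "n_contigs": int(len(features)),
        "n_labeled_w": int((labeled["label"] == "W").sum()),
        "n_labeled_nonw": int((labeled["label"] == "NONW").sum()),
        "n_to_classify": int(len(to_classify)),
        "n_eligible": int(features["eligible"].sum()),
    }

    def _stats():
        if labeled.empty or labeled[labeled["eligible"]].empty:
            logger.warning("no labeled contigs; separation stats skipped")
            return None
        report = separation_stats.separation_report(
            labeled, B=config.B, level=config.ci_level, seed=config.seed)
        with open(out / "separation_report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
        return report

    manifest["separation"] = stage("stats", _stats)

    def _train():
        pool = labeled[labeled["eligible"]]
        model = bayes_classifier.train(
            pool, bin_width=config.bin_width, epsilon=config.epsilon,
            prior_w=config.prior_w, mode=config.mode,
            skip_incomplete_bins=True, fit_pooled=True)
        bayes_classifier.save_model(model, out / "model.json")
        return model

    model = stage("train", _train)

    def _classify():
        target = to_classify if not to_classify.empty else features
        calls = bayes_classifier.classify(target, model, tau=config.tau,
                                          pooled_fallback=True)
        df = bayes_classifier.calls_to_frame(calls)
        df.to_csv(out / "calls.tsv", sep="\t", index=False)
        return df

    calls = stage("classify", _classify)
    manifest["counts"]["n_called_w"] = int((calls["call"] == "W").sum()) if not calls.empty else 0

    manifest["complete"] = True
    _write_manifest(manifest, out)
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
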