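"""Length-conditioned naive Bayes classifier over (coverage, read depth).

Each contig is summarized by X = (x1, x2) — coverage and read depth — and
assigned a posterior probability of being W-specific. Features are assumed
conditionally independent given the class, and all distributions are
conditioned on the contig's 500-bp length bin L, because short contigs have
near-zero features regardless of class. Class-conditional feature
distributions are discretized into equal-width bins estimated as relative
frequencies from the training set, with a small epsilon added to every bin
so unseen feature values never zero out a likelihood.

Two posterior modes are provided:

* ``standard_bayes`` (default):
  ``π·P(X|W,L) / (π·P(X|W,L) + (1−π)·P(X|nonW,L))``
* ``as_printed``: ``π·P(X|W,L) / (P(X|W,L) + P(X|nonW,L))`` — a variant
  sometimes written with the priors omitted from the denominator. Note this
  form is bounded above by π, so with π = 0.5 it cannot clear a 0.95 call
  threshold; it is retained for comparability, not recommended.

Likelihood arithmetic is carried in log space; results agree with direct
products to ~1e-15 relative.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .length_models import DEFAULT_BIN_WIDTH, length_bin

logger = logging.getLogger(__name__)

MODES = ("standard_bayes", "as_printed")
CLASSES = ("W", "NONW")

MODEL_FORMAT_VERSION = 1


def discretize(x: float, w: float) -> int:
    """Feature-bin index k with k·w <= x < (k+1)·w (half-open convention).

    A tiny relative tolerance keeps exact bin boundaries (e.g. x = 0.005 at
    w = 0.005) in the upper bin despite floating-point division.
    """
    if x < 0:
        raise ValueError("feature values must be non-negative")
    if w <= 0:
        raise ValueError("bin width must be positive")
    return int(math.floor(x / w + 1e-9))


@dataclass
class FeatureDistribution:
    """Smoothed discretized distribution of one feature for one (class, L)."""

    cls: str
    L: int
    width: float
    epsilon: float
    freqs: dict[int, float]  # raw relative frequencies; sum to 1 over seen bins

    def prob(self, bin_index: int) -> float:
        """Smoothed probability: raw frequency of the bin plus epsilon."""
        return self.freqs.get(bin_index, 0.0) + self.epsilon


@dataclass
class ClassifierModel:
    bin_width: float
    epsilon: float
    prior_w: float
    mode: str
    length_bin_width: int
    # tables[L][cls] = (x1 distribution, x2 distribution)
    tables: dict[int, dict[str, tuple[FeatureDistribution, FeatureDistribution]]]
    pooled: dict[str, tuple[FeatureDistribution, FeatureDistribution]] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def length_bins(self) -> list[int]:
        return sorted(self.tables)


@dataclass(frozen=True)
class WCall:
    contig_id: str
    L: int
    x1: float
    x2: float
    posterior_w: float
    is_w: bool
    used_pooled: bool = False


def _fit_distribution(values: np.ndarray, cls: str, L: int, width: float,
                      epsilon: float) -> FeatureDistribution:
    bins = [discretize(float(v), width) for v in values]
    counts: dict[int, int] = {}
    for b in bins:
        counts[b] = counts.get(b, 0) + 1
    n = len(bins)
    return FeatureDistribution(cls, L, width, epsilon,
                               {b: c / n for b, c in counts.items()})


def train(
    features: pd.DataFrame,
    bin_width: float = 0.005,
    epsilon: float = 1e-6,
    prior_w: float | None = None,
    mode: str = "standard_bayes",
    length_bin_width: int = DEFAULT_BIN_WIDTH,
    skip_incomplete_bins: bool = False,
    fit_pooled: bool = True,
) -> ClassifierModel:
    """Estimate per-(class, L) feature tables from labeled training features.

    ``features`` needs columns label ("W"/"NONW"), x1, x2 and either an L
    column (length bin) or unmasked_len from which L is derived. A length
    bin where one class is absent is a hard error unless
    ``skip_incomplete_bins`` is set (then it is dropped with a log entry —
    used by resampling harnesses where random draws may miss a bin).
    The default prior π is the W proportion of the training set.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if bin_width <= 0 or epsilon <= 0:
        raise ValueError("bin_width and epsilon must be positive")
    df = features.copy()
    if "L" not in df.columns:
        df["L"] = df["unmasked_len"].map(lambda v: length_bin(int(v), length_bin_width))
    bad = set(df["label"]) - set(CLASSES)
    if bad:
        raise ValueError(f"training labels must be W/NONW; got {sorted(bad)}")

    tables: dict[int, dict[str, tuple[FeatureDistribution, FeatureDistribution]]] = {}
    for L, group in df.groupby("L"):
        per_class = {}
        missing = [c for c in CLASSES if (group["label"] == c).sum() == 0]
        if missing:
            if skip_incomplete_bins:
                logger.info("dropping length bin %d (missing class %s)", L, missing)
                continue
            raise ValueError(f"class {missing} absent from training set at length bin {L}")
        for cls in CLASSES:
            sub = group[group["label"] == cls]
            per_class[cls] = (
                _fit_distribution(sub["x1"].to_numpy(), cls, int(L), bin_width, epsilon),
                _fit_distribution(sub["x2"].to_numpy(), cls, int(L), bin_width, epsilon),
            )
        tables[int(L)] = per_class
    if not tables:
        if not (skip_incomplete_bins and fit_pooled):
            raise ValueError("no complete length bin in training set")
        # resampling harnesses with tiny draws can miss every bin; the model
        # is then pooled-only, and every call is flagged as such
        logger.warning("no length bin contains both classes; model is pooled-only")

    pooled = None
    if fit_pooled:
        missing = [c for c in CLASSES if (df["label"] == c).sum() == 0]
        if missing:
            raise ValueError(f"class {missing} absent from training set")
        pooled = {}
        for cls in CLASSES:
            sub = df[df["label"] == cls]
            pooled[cls] = (
                _fit_distribution(sub["x1"].to_numpy(), cls, -1, bin_width, epsilon),
                _fit_distribution(sub["x2"].to_numpy(), cls, -1, bin_width, epsilon),
            )

    if prior_w is None:
        prior_w = float((df["label"] == "W").mean())
    if not 0 < prior_w < 1:
        raise ValueError("prior_w must be in (0, 1)")

    provenance = {
        "n_training": int(len(df)),
        "n_w": int((df["label"] == "W").sum()),
        "n_nonw": int((df["label"] == "NONW").sum()),
        "length_bins": sorted(int(k) for k in tables),
    }
    return ClassifierModel(bin_width, epsilon, float(prior_w), mode,
                           length_bin_width, tables, pooled, provenance)


def _log_likelihood(dists, x1: float, x2: float, width: float) -> float:
    d1, d2 = dists
    return math.log(d1.prob(discretize(x1, width))) + math.log(d2.prob(discretize(x2, width)))


def posterior_w(x, model: ClassifierModel, L: int | None = None,
                use_pooled: bool = False) -> float:
    """Posterior probability that a contig with features x is W-specific.

    ``x`` is a FeatureVector-like object (attributes x1, x2, unmasked_len)
    or an (x1, x2) pair with L given explicitly. A missing length bin is a
    hard error; pass ``use_pooled=True`` to score with the explicit pooled
    (length-agnostic) table instead.
    """
    if hasattr(x, "x1"):
        x1, x2 = float(x.x1), float(x.x2)
        if L is None:
            L = length_bin(int(x.unmasked_len), model.length_bin_width)
    else:
        x1, x2 = float(x[0]), float(x[1])
        if L is None and not use_pooled:
            raise ValueError("L required when passing bare (x1, x2)")

    if use_pooled:
        if model.pooled is None:
            raise KeyError("model has no pooled table")
        dists = model.pooled
    else:
        if L not in model.tables:
            raise KeyError(
                f"no trained table for length bin {L}; "
                f"available bins: {model.length_bins}"
            )
        dists = model.tables[L]

    lw = _log_likelihood(dists["W"], x1, x2, model.bin_width)
    lnw = _log_likelihood(dists["NONW"], x1, x2, model.bin_width)
    pi = model.prior_w
    if model.mode == "standard_bayes":
        a = math.log(pi) + lw
        b = math.log1p(-pi) + lnw
        return float(1.0 / (1.0 + math.exp(b - a)))
    # as printed: pi * P(X|W) / (P(X|W) + P(X|nonW))
    m = max(lw, lnw)
    denom = math.exp(lw - m) + math.exp(lnw - m)
    return float(pi * math.exp(lw - m) / denom)


def classify(features: pd.DataFrame, model: ClassifierModel, tau: float = 0.95,
             pooled_fallback: bool = False) -> list[WCall]:
    """Score every eligible contig; predicted W iff posterior > tau.

    Ineligible contigs (no possible placement) are excluded from the calls
    and reported through the log. Calls are sorted by descending posterior
    (contig id breaking ties, for reproducibility). With
    ``pooled_fallback``, contigs whose length bin is untrained are scored
    with the pooled table and flagged in the call.
    """
    excluded = features[~features["eligible"]]["contig_id"].tolist() \
        if "eligible" in features.columns else []
    if excluded:
        logger.warning("%d ineligible contigs excluded from classification: %s%s",
                       len(excluded), excluded[:5], "..." if len(excluded) > 5 else "")
    df = features[features["eligible"]] if "eligible" in features.columns else features
    calls = []
    for row in df.itertuples(index=False):
        L = length_bin(int(row.unmasked_len), model.length_bin_width)
        pooled = False
        if L not in model.tables and pooled_fallback:
            pooled = True
        p = posterior_w((row.x1, row.x2), model, L=L, use_pooled=pooled)
        calls.append(WCall(row.contig_id, L, float(row.x1), float(row.x2),
                           p, p > tau, pooled))
    calls.sort(key=lambda c: (-c.posterior_w, c.contig_id))
    return calls


def calls_to_frame(calls: list[WCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"contig_id": c.contig_id, "L": c.L, "x1": c.x1, "x2": c.x2,
             "posterior_w": c.posterior_w, "call": "W" if c.is_w else "NONW",
             "used_pooled": c.used_pooled}
            for c in calls
        ]
    )


# ---------------------------------------------------------------------------
# model (de)serialization


def _dist_to_json(d: FeatureDistribution) -> dict:
    return {"cls": d.cls, "L": d.L, "width": d.width, "epsilon": d.epsilon,
            "freqs": {str(k): v for k, v in sorted(d.freqs.items())}}


def _dist_from_json(obj: dict) -> FeatureDistribution:
    return FeatureDistribution(obj["cls"], obj["L"], obj["width"], obj["epsilon"],
                               {int(k): v for k, v in obj["freqs"].items()})


def save_model(model: ClassifierModel, path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "bin_width": model.bin_width,
        "epsilon": model.epsilon,
        "prior_w": model.prior_w,
        "mode": model.mode,
        "length_bin_width": model.length_bin_width,
        "tables": {
            str(L): {cls: [_dist_to_json(d) for d in dists]
                     for cls, dists in per_class.items()}
            for L, per_class in model.tables.items()
        },
        "pooled": None if model.pooled is None else {
            cls: [_dist_to_json(d) for d in dists] for cls, dists in model.pooled.items()
        },
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)


def load_model(path) -> ClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')}")
    tables = {
        int(L): {cls: tuple(_dist_from_json(d) for d in dists)
                 for cls, dists in per_class.items()}
        for L, per_class in doc["tables"].items()
    }
    pooled = None
    if doc["pooled"] is not None:
        pooled = {cls: tuple(_dist_from_json(d) for d in dists)
                  for cls, dists in doc["pooled"].items()}
    return ClassifierModel(doc["bin_width"], doc["epsilon"], doc["prior_w"],
                           doc["mode"], doc["length_bin_width"], tables, pooled,
                           doc.get("provenance", {}))
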