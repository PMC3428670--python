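"""Bootstrap confidence intervals and the quantile-separation test.

The method's central empirical claim is that W contigs occupy a feature
region (coverage and read depth near zero) disjoint from autosomal/Z-linked
contigs. That is established non-parametrically:

* percentile bootstrap CIs of the mean of each feature per group;
* a quantile-separation test: per bootstrap replicate, resample both groups
  (contigs resampled jointly, preserving the x1–x2 dependence) and take
  ``min(non-W resample) − max(W resample)``. If the groups are distinctly
  separated this difference is positive in (nearly) every replicate; the
  reported p is the fraction of replicates where it is not.
* the false-positive-rate-by-length curve: the fraction of known non-W
  fragments whose coverage falls below the W coverage ceiling, per length
  bin — short fragments are far more likely to look W-like by chance.

Sign convention: positive difference = separated. The literal opposite-order
difference is recorded alongside with flipped sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_stream

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    statistic: str
    B: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    replicates: np.ndarray


@dataclass
class SeparationResult:
    """Per-replicate separation differences and the overlap fraction p."""

    diffs: np.ndarray          # min(non-W resample) - max(W resample), per replicate
    p: float                   # fraction of replicates with diff <= 0
    B: int

    @property
    def diffs_literal_order(self) -> np.ndarray:
        """max(W) − min(non-W), i.e. the same statistic with flipped sign."""
        return -self.diffs

    @property
    def p_label(self) -> str:
        """p for reporting; exact zero is stated as a bound, not a claim."""
        return f"<{1 / self.B:g}" if self.p == 0 else f"{self.p:g}"


def bootstrap_ci(values, B: int = 1000, level: float = 0.95, seed: int = 0,
                 statistic: str = "mean") -> BootstrapResult:
    """Percentile bootstrap CI of the mean from B with-replacement resamples."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("bootstrap_ci requires non-empty input")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng_stream(seed, f"bootstrap-{statistic}")
    idx = rng.integers(0, v.size, size=(B, v.size))
    reps = v[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    return BootstrapResult(statistic, B, float(v.mean()), float(lo), float(hi), level, reps)


def quantile_separation_test(w_values, nonw_values, B: int = 1000, seed: int = 0
                             ) -> SeparationResult:
    """Bootstrap test of whether non-W values sit distinctly above W values."""
    w = np.asarray(w_values, dtype=float)
    nw = np.asarray(nonw_values, dtype=float)
    if w.size == 0 or nw.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = rng_stream(seed, "quantile-separation")
    w_max = w[rng.integers(0, w.size, size=(B, w.size))].max(axis=1)
    nw_min = nw[rng.integers(0, nw.size, size=(B, nw.size))].min(axis=1)
    diffs = nw_min - w_max
    p = float((diffs <= 0).mean())
    return SeparationResult(diffs, p, B)


def w_coverage_threshold(w_coverages, B: int = 1000, seed: int = 0) -> float:
    """Mean over bootstrap replicates of the maximum W coverage in the resample.

    This is the coverage ceiling below which a contig looks W-like; it feeds
    the false-positive-rate-by-length curve.
    """
    w = np.asarray(w_coverages, dtype=float)
    if w.size == 0:
        raise ValueError("w_coverage_threshold requires non-empty input")
    rng = rng_stream(seed, "w-coverage-threshold")
    return float(w[rng.integers(0, w.size, size=(B, w.size))].max(axis=1).mean())


def fpr_by_length(features_by_length: dict[int, pd.DataFrame], threshold: float
                  ) -> list[tuple[int, float]]:
    """Per length bin, the fraction of non-W fragments with coverage < threshold."""
    out = []
    for L in sorted(features_by_length):
        df = features_by_length[L]
        if df.empty or "label" not in df.columns:
            logger.warning("length bin %d has no fragments at all; omitted", L)
            continue
        nonw = df[(df["label"] == "NONW") & df["eligible"]]
        if nonw.empty:
            logger.warning("length bin %d has no eligible non-W fragments; omitted", L)
            continue
        out.append((L, float((nonw["x1"] < threshold).mean())))
    return out


def separation_report(features: pd.DataFrame, B: int = 1000, level: float = 0.95,
                      seed: int = 0) -> dict:
    """Bootstrap CIs and separation tests for both features, as one dict."""
    eligible = features[features["eligible"]]
    w = eligible[eligible["label"] == "W"]
    nonw = eligible[eligible["label"] == "NONW"]
    report: dict = {"B": B, "level": level, "seed": seed,
                    "n_w": int(len(w)), "n_nonw": int(len(nonw))}
    for feat, name in (("x1", "coverage"), ("x2", "read_depth")):
        for group, gname in ((w, "w"), (nonw, "nonw")):
            ci = bootstrap_ci(group[feat].to_numpy(), B=B, level=level, seed=seed,
                              statistic=f"{gname}-{name}")
            report[f"{gname}_{name}_mean"] = ci.estimate
            report[f"{gname}_{name}_ci_low"] = ci.ci_low
            report[f"{gname}_{name}_ci_high"] = ci.ci_high
        sep = quantile_separation_test(w[feat].to_numpy(), nonw[feat].to_numpy(),
                                       B=B, seed=seed)
        report[f"separation_p_{name}"] = sep.p
        report[f"separation_p_{name}_label"] = sep.p_label
    return report
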