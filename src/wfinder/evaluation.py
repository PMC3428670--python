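"""ROC/AUC machinery and the classifier performance experiments.

Three experiment harnesses mirror the questions that matter for deploying
the classifier: how much labeled training data is needed (training-set
size), how sensitive performance is to class imbalance (non-W:W ratio), and
whether training-contig length must match the contigs being classified
(length transfer, against the length-conditioned classifier). All are
driven by repeated random train/validation splits with one master seed and
per-iteration derived streams, so every grid is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_stream
from .bayes_classifier import ClassifierModel, posterior_w, train
from .length_models import length_bin

logger = logging.getLogger(__name__)


@dataclass
class RocPoints:
    """ROC curve points over all distinct score thresholds, plus the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class ExperimentGrid:
    factor: str
    levels: list
    mean_auc: list[float]
    sd_auc: list[float]
    aucs: np.ndarray  # (level, iteration)
    iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.factor,
            "level": [str(v) for v in self.levels],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
        })


def roc_curve(scores, labels) -> RocPoints:
    """Tie-grouped ROC curve with trapezoidal AUC.

    ``labels`` are truthy for the positive (W) class. Tied scores move the
    curve diagonally in one step, which makes the trapezoidal area equal to
    the pairwise-concordance (rank) statistic with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # indices where the threshold changes (group ties)
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    cut = np.concatenate([distinct, [s_sorted.size - 1]])
    tps = np.cumsum(y_sorted)[cut]
    fps = np.cumsum(~y_sorted)[cut]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    area = float(np.trapezoid(tpr, fpr))
    return RocPoints(fpr, tpr, thresholds, area)


def auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve (equals the rank statistic)."""
    return roc_curve(scores, labels).auc


# ---------------------------------------------------------------------------
# scoring helpers


def _score_frame(df: pd.DataFrame, model: ClassifierModel,
                 L_override: int | None = None) -> np.ndarray:
    """Posteriors for every row; optionally force one length-bin table."""
    scores = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        if L_override is not None:
            scores[i] = posterior_w((row.x1, row.x2), model, L=L_override)
        else:
            L = length_bin(int(row.unmasked_len), model.length_bin_width)
            pooled = L not in model.tables
            scores[i] = posterior_w((row.x1, row.x2), model, L=L, use_pooled=pooled)
    return scores


def _sample_split(pool: pd.DataFrame, n_w: int, n_nonw: int,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint (train, validation) split with fixed per-class training counts."""
    w_idx = np.flatnonzero((pool["label"] == "W").to_numpy())
    nonw_idx = np.flatnonzero((pool["label"] == "NONW").to_numpy())
    if len(w_idx) <= n_w or len(nonw_idx) <= n_nonw:
        raise ValueError(
            f"pool too small for split: need >{n_w} W and >{n_nonw} non-W, "
            f"have {len(w_idx)} / {len(nonw_idx)}"
        )
    w_train = rng.choice(w_idx, size=n_w, replace=False)
    nonw_train = rng.choice(nonw_idx, size=n_nonw, replace=False)
    train_rows = np.zeros(len(pool), dtype=bool)
    train_rows[w_train] = True
    train_rows[nonw_train] = True
    return pool[train_rows], pool[~train_rows]


@dataclass
class CrossValResult:
    mean_auc: float
    sd_auc: float
    aucs: np.ndarray
    n_w: int
    ratio: float
    rerolled: int = 0


def cross_validate(
    features: pd.DataFrame,
    n_w: int,
    ratio: float = 1.0,
    bin_width: float = 0.005,
    iterations: int = 100,
    seed: int = 0,
    epsilon: float = 1e-6,
    mode: str = "standard_bayes",
) -> CrossValResult:
    """Repeated random-split cross-validation of the length-conditioned classifier.

    Per iteration: draw n_w W and round(ratio*n_w) non-W training contigs,
    train on them (bins missing a class are dropped; validation contigs in
    untrained bins are scored with the recorded pooled table), score the
    remainder, and compute the AUC. An iteration whose validation fold loses
    a class is rerolled (logged).
    """
    pool = features[features["eligible"]].reset_index(drop=True)
    n_nonw = int(round(ratio * n_w))
    aucs = np.empty(iterations)
    rerolled = 0
    for i in range(iterations):
        for attempt in range(100):
            rng = rng_stream(seed, f"cv-{i}-{attempt}")
            train_df, val_df = _sample_split(pool, n_w, n_nonw, rng)
            if (val_df["label"] == "W").any() and (val_df["label"] == "NONW").any():
                break
            rerolled += 1
            logger.info("cv iteration %d attempt %d: single-class validation, rerolling", i, attempt)
        else:
            raise RuntimeError("could not draw a two-class validation fold")
        model = train(train_df, bin_width=bin_width, epsilon=epsilon, mode=mode,
                      skip_incomplete_bins=True, fit_pooled=True)
        scores = _score_frame(val_df, model)
        aucs[i] = auc(scores, (val_df["label"] == "W").to_numpy())
    return CrossValResult(float(aucs.mean()), float(aucs.std(ddof=1)) if iterations > 1 else 0.0,
                          aucs, n_w, ratio, rerolled)


def size_experiment(features: pd.DataFrame, sizes: list[int], iterations: int = 100,
                    seed: int = 0, ratio: float = 1.0, bin_width: float = 0.005
                    ) -> ExperimentGrid:
    """Mean cross-validated AUC as a function of per-class training-set size."""
    aucs = np.empty((len(sizes), iterations))
    for j, n_w in enumerate(sizes):
        res = cross_validate(features, n_w=n_w, ratio=ratio, bin_width=bin_width,
                             iterations=iterations, seed=seed)
        aucs[j] = res.aucs
    return ExperimentGrid("training_size", list(sizes), aucs.mean(axis=1).tolist(),
                          aucs.std(axis=1, ddof=1).tolist(), aucs, iterations, seed)


def imbalance_experiment(features: pd.DataFrame, ratios: list[float], n_w: int = 50,
                         iterations: int = 100, seed: int = 0,
                         bin_width: float = 0.005, val_frac: float = 0.3
                         ) -> ExperimentGrid:
    """Mean AUC by non-W:W training ratio, on identical validation sets per iteration.

    The validation set of each iteration is drawn from a level-independent
    stream, so every ratio level is scored on exactly the same contigs.
    """
    if any(r < 1 for r in ratios):
        raise ValueError("ratios must be >= 1")
    pool = features[features["eligible"]].reset_index(drop=True)
    levels = []
    rows = []
    for ratio in ratios:
        n_nonw = int(round(ratio * n_w))
        avail_nonw = int((pool["label"] == "NONW").sum() * (1 - val_frac))
        if n_nonw > avail_nonw:
            logger.warning("ratio %s infeasible (%d non-W needed, ~%d available); skipped",
                           ratio, n_nonw, avail_nonw)
            continue
        levels.append(ratio)
    aucs = np.empty((len(levels), iterations))
    for i in range(iterations):
        vrng = rng_stream(seed, f"imbalance-val-{i}")
        val_rows = np.zeros(len(pool), dtype=bool)
        for cls in ("W", "NONW"):
            idx = np.flatnonzero((pool["label"] == cls).to_numpy())
            n_val = max(1, int(round(val_frac * idx.size)))
            val_rows[vrng.choice(idx, size=n_val, replace=False)] = True
        val_df = pool[val_rows]
        rest = pool[~val_rows].reset_index(drop=True)
        for j, ratio in enumerate(levels):
            trng = rng_stream(seed, f"imbalance-train-{i}-{ratio}")
            n_nonw = int(round(ratio * n_w))
            w_idx = np.flatnonzero((rest["label"] == "W").to_numpy())
            nonw_idx = np.flatnonzero((rest["label"] == "NONW").to_numpy())
            take = np.concatenate([
                trng.choice(w_idx, size=min(n_w, w_idx.size), replace=False),
                trng.choice(nonw_idx, size=min(n_nonw, nonw_idx.size), replace=False),
            ])
            model = train(rest.iloc[np.sort(take)], bin_width=bin_width,
                          skip_incomplete_bins=True, fit_pooled=True)
            scores = _score_frame(val_df, model)
            aucs[j, i] = auc(scores, (val_df["label"] == "W").to_numpy())
        rows.append(i)
    return ExperimentGrid("nonw_to_w_ratio", levels, aucs.mean(axis=1).tolist(),
                          aucs.std(axis=1, ddof=1).tolist(), aucs, iterations, seed)


def length_transfer_experiment(
    train_by_length: dict[int, pd.DataFrame],
    validation: pd.DataFrame,
    lengths: list[int] | None = None,
    iterations: int = 100,
    seed: int = 0,
    n_per_class: int = 200,
    bin_width: float = 0.005,
) -> ExperimentGrid:
    """Fixed-training-length classifiers vs the length-conditioned classifier.

    Each fixed level L trains only on L-length fragments and scores every
    validation contig with that single table (no length conditioning). The
    final level, "conditioned", trains one table per length and scores each
    validation contig with its own length bin. All levels share the same
    validation set.
    """
    if lengths is None:
        lengths = sorted(train_by_length)
    val_df = validation[validation["eligible"]]
    y = (val_df["label"] == "W").to_numpy()
    levels: list = list(lengths) + ["conditioned"]
    aucs = np.empty((len(levels), iterations))
    for i in range(iterations):
        sampled: dict[int, pd.DataFrame] = {}
        for L in lengths:
            rng = rng_stream(seed, f"length-transfer-{i}-{L}")
            pool = train_by_length[L]
            pool = pool[pool["eligible"]].reset_index(drop=True)
            parts = []
            for cls in ("W", "NONW"):
                idx = np.flatnonzero((pool["label"] == cls).to_numpy())
                if idx.size == 0:
                    raise ValueError(f"no {cls} fragments available at training length {L}")
                parts.append(pool.iloc[np.sort(rng.choice(
                    idx, size=min(n_per_class, idx.size), replace=False))])
            sampled[L] = pd.concat(parts, ignore_index=True)
        for j, L in enumerate(lengths):
            df = sampled[L].copy()
            df["L"] = L
            model = train(df, bin_width=bin_width, fit_pooled=False)
            aucs[j, i] = auc(_score_frame(val_df, model, L_override=L), y)
        combined = pd.concat(
            [sampled[L].assign(L=L) for L in lengths], ignore_index=True)
        model = train(combined, bin_width=bin_width, skip_incomplete_bins=True,
                      fit_pooled=True)
        aucs[-1, i] = auc(_score_frame(val_df, model), y)
    return ExperimentGrid("training_length", levels, aucs.mean(axis=1).tolist(),
                          aucs.std(axis=1, ddof=1).tolist(), aucs, iterations, seed)


# ---------------------------------------------------------------------------
# output


def write_roc_tsv(roc: RocPoints, path) -> None:
    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
                 ).to_csv(path, sep="\t", index=False)


def write_grid_tsv(grid: ExperimentGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)


def plot_grid(grid: ExperimentGrid, path) -> None:
    """Mean AUC (± SD) against the experiment factor, as a simple line plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(grid.levels))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(x, grid.mean_auc, yerr=grid.sd_auc, marker="o")
    ax.set_xticks(x)
    ax.set_xticklabels([str(v) for v in grid.levels], rotation=45)
    ax.set_xlabel(grid.factor)
    ax.set_ylabel("mean AUC")
    ax.set_ylim(0.0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(roc: RocPoints, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr)
    ax.plot([0, 1], [0, 1], ls="--", c="gray")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {roc.auc:.4f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
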