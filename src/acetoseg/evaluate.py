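"""Evaluation protocol: pixel metrics, ROC/AUC, LOOCV, and arm comparison.

Segmentation quality is scored per pixel against the ground-truth mask:
accuracy, recall, precision and F1 (the F1 score of binary masks equals the
dice coefficient).  Because no held-out test set exists at this cohort size,
validation follows leave-one-out cross-validation, metrics are averaged over
a tail window of epochs where training has converged, and the ROC AUC is
read at the epoch with the smallest validation loss.  The two arms —
dual-input ("proposed") versus after-image-only ("control") — are compared
with Welch's t-test across experiment repeats and Wilcoxon's signed-rank
test across cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "ArmComparison",
    "confusion",
    "metrics",
    "roc_auc",
    "default_epoch_window",
    "epoch_window_mean",
    "min_loss_epoch",
    "loocv",
    "welch_t",
    "wilcoxon_signed_rank",
    "compare_arms",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "recall", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts; foreground (positive) is acetowhite epithelium."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricRecord:
    """Pixel metrics; a ratio with zero denominator is None (undefined)."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None
    scope: Literal["per_case", "per_experiment"] = "per_case"

    def as_dict(self) -> dict[str, float]:
        return {
            k: (np.nan if getattr(self, k) is None else getattr(self, k))
            for k in METRIC_NAMES
        }


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Element-wise confusion counts of two binary masks."""
    pred = _check_binary(pred_mask, "pred_mask")
    truth = _check_binary(truth_mask, "truth_mask")
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts, scope: str = "per_case") -> MetricRecord:
    """accuracy=(tp+tn)/N, recall=tp/(tp+fn), precision=tp/(tp+fp),
    f1 = harmonic mean of recall and precision (= dice coefficient).

    Undefined ratios (zero denominator) come back as None and are excluded
    from downstream averages.
    """
    if counts.total == 0:
        raise ValidationError("confusion counts are all zero")
    acc = (counts.tp + counts.tn) / counts.total
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    if prec is None or rec is None:
        f1 = None
    elif prec + rec == 0:
        f1 = 0.0
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return MetricRecord(accuracy=acc, recall=rec, precision=prec, f1=f1, scope=scope)


def roc_auc(
    prob_map: np.ndarray | Sequence[np.ndarray],
    truth_mask: np.ndarray | Sequence[np.ndarray],
) -> float:
    """Pixel-pooled ROC AUC by the rank (Mann-Whitney) formulation.

    Ties receive midranks, so AUC equals the probability that a random
    positive pixel outscores a random negative one, counting ties as 1/2.
    """
    if isinstance(prob_map, np.ndarray) and prob_map is not None and prob_map.ndim <= 2:
        prob_map, truth_mask = [prob_map], [truth_mask]
    scores = np.concatenate([np.asarray(p, dtype=float).ravel() for p in prob_map])
    labels = np.concatenate(
        [_check_binary(t, "truth_mask").ravel() for t in truth_mask]
    )
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one positive and one negative pixel")
    ranks = scipy.stats.rankdata(scores)  # midranks for ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ------------------------------------------------------- history reduction

def default_epoch_window(n_epochs: int) -> tuple[int, int]:
    """Converged-tail window: the final 10% of epochs (inclusive, 1-based).

    At 500 epochs this is [450, 500], the canonical evaluation window; for
    shorter schedules the same fraction of the tail is kept.
    """
    lo = n_epochs - int(round(0.1 * n_epochs))
    return max(1, lo), n_epochs


def epoch_window_mean(history, window: tuple[int, int]) -> MetricRecord:
    """Arithmetic mean of each validation metric over epochs lo..hi
    (1-based, inclusive); undefined epochs are excluded from the mean."""
    lo, hi = window
    n = len(history.train_loss)
    if not (1 <= lo <= hi <= n):
        raise ValidationError(f"window {window} outside recorded epochs 1..{n}")
    sl = slice(lo - 1, hi)
    out = {}
    for name in METRIC_NAMES:
        vals = np.asarray(getattr(history, name)[sl], dtype=float)
        n_undef = int(np.isnan(vals).sum())
        if n_undef:
            logger.debug("window %s: %d undefined %s epochs excluded", window, n_undef, name)
        out[name] = float(np.nanmean(vals)) if n_undef < vals.size else None
    return MetricRecord(scope="per_case", **out)


def min_loss_epoch(history, key: str = "val_loss") -> int:
    """1-based epoch with the smallest loss; earliest epoch on ties."""
    losses = np.asarray(getattr(history, key), dtype=float)
    if losses.size == 0:
        raise ValidationError("empty history")
    return int(np.argmin(losses)) + 1


# ------------------------------------------------------------------- LOOCV

def fold_seed(experiment_seed: int, fold_index: int) -> int:
    """Stable per-fold seed derived from (experiment seed, fold index)."""
    return int(
        np.random.SeedSequence([experiment_seed, fold_index]).generate_state(1)[0]
        % (2 ** 31)
    )


def loocv(cases, config, augment_params=None, experiment_seed: int = 0,
          progress: bool = False):
    """Leave-one-out cross-validation: fold i trains on all cases but i and
    validates on case i.  Returns one TrainingHistory per case, in dataset
    order."""
    from . import model as _model  # deferred: model imports this module

    n = len(cases)
    if n < 2:
        raise ValidationError(f"LOOCV needs at least 2 cases, got {n}")
    histories = []
    for i in range(n):
        cfg = replace(config, seed=fold_seed(experiment_seed, i))
        train_cases = [c for j, c in enumerate(cases) if j != i]
        _, hist = _model.train(train_cases, cases[i], cfg, augment_params)
        histories.append(hist)
        if progress:
            logger.info("fold %d/%d (val=%s) done", i + 1, n, cases[i].case_id)
    return histories


# -------------------------------------------------------------- statistics

def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValidationError("both samples have zero variance")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; |differences| are ranked with midranks.
    The statistic W is the smaller of the positive- and negative-rank sums
    (so W = 0 when every difference has the same sign).  The p-value is
    exact for n <= 25 without tied ranks, otherwise a normal approximation
    with continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("all paired differences are zero")
    if d.size < 5:
        raise ValidationError(
            f"need >= 5 nonzero differences for a meaningful test, got {d.size}"
        )
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------- arm comparison

@dataclass
class ArmComparison:
    """All aggregates of a proposed-vs-control comparison.

    ``per_experiment[arm]`` is a (n_experiments x metric) frame of means
    across cases (these feed Welch's t-test); ``per_case[arm]`` is a
    (n_cases x metric) frame of means across experiments (these feed the
    Wilcoxon signed-rank test).  AUC is computed per fold at the epoch of
    minimum validation loss and aggregated the same way.
    """

    arms: tuple[str, ...]
    n_experiments: int
    case_ids: tuple[str, ...]
    per_experiment: dict[str, pd.DataFrame]
    per_case: dict[str, pd.DataFrame]
    welch: pd.DataFrame | None
    wilcoxon: pd.DataFrame | None
    records: pd.DataFrame = field(repr=False, default=None)

    def arm_mean(self, arm: str, metric: str) -> float:
        return float(self.per_experiment[arm][metric].mean())

    def arm_sd(self, arm: str, metric: str) -> float:
        return float(self.per_experiment[arm][metric].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD over experiments per arm, with Welch p-values."""
        rows = []
        for metric in list(METRIC_NAMES) + ["auc"]:
            row = {"metric": metric}
            for arm in self.arms:
                row[f"{arm}_mean"] = self.arm_mean(arm, metric)
                row[f"{arm}_sd"] = self.arm_sd(arm, metric)
            if self.welch is not None and metric in self.welch.index:
                row["welch_t"] = self.welch.loc[metric, "t"]
                row["welch_p"] = self.welch.loc[metric, "p"]
            rows.append(row)
        return pd.DataFrame(rows).set_index("metric")


def _fold_measurements(histories, window_override=None):
    """Per-fold window-averaged metrics plus AUC at the min-val-loss epoch."""
    rows = []
    for hist in histories:
        window = window_override or default_epoch_window(len(hist.train_loss))
        rec = epoch_window_mean(hist, window).as_dict()
        e_star = min_loss_epoch(hist)
        probs = hist.val_probs[e_star - 1]
        rec["auc"] = np.nan
        rows.append((rec, probs, e_star))
    return rows


def compare_arms(
    cases,
    config,
    n_experiments: int,
    augment_params=None,
    base_seed: int = 0,
    arms: Sequence[str] = ("proposed", "control"),
    pooling: str = "case_mean",
    window: tuple[int, int] | None = None,
    progress: bool = False,
) -> ArmComparison:
    """Run the full repeated-LOOCV comparison of the two input arms.

    Experiment e (0-based) uses seed ``base_seed + e`` for BOTH arms, so the
    arms see identical folds, batch orders and augmentations, and differ only
    in their input channels.  ``pooling`` controls how an experiment's
    summary metric is formed: ``case_mean`` averages the per-case metrics,
    ``pixel_pooled`` sums confusion counts over all validation cases first.
    """
    if n_experiments < 1:
        raise ValidationError("n_experiments must be >= 1")
    for arm in arms:
        if arm not in ("proposed", "control"):
            raise ValidationError(f"unknown arm {arm!r}")
    if pooling not in ("case_mean", "pixel_pooled"):
        raise ValidationError(f"unknown pooling {pooling!r}")

    records = []  # tidy rows: experiment, case, arm, metric, value
    case_ids = tuple(c.case_id for c in cases)
    masks = [np.asarray(c.mask, dtype=np.uint8) for c in cases]
    threshold = getattr(config, "threshold", 0.5)

    for e in range(n_experiments):
        exp_seed = base_seed + e
        for arm in arms:
            cfg = replace(config, in_channels=6 if arm == "proposed" else 3)
            histories = loocv(
                cases, cfg, augment_params, experiment_seed=exp_seed, progress=progress
            )
            win = window or default_epoch_window(len(histories[0].train_loss))
            if pooling == "case_mean":
                for i, hist in enumerate(histories):
                    rec = epoch_window_mean(hist, win).as_dict()
                    for metric, value in rec.items():
                        records.append((e, case_ids[i], arm, metric, value))
            else:  # pixel_pooled: re-threshold stored maps, pool counts per epoch
                per_epoch = []
                for ep in range(win[0], win[1] + 1):
                    counts = ConfusionCounts(0, 0, 0, 0)
                    for i, hist in enumerate(histories):
                        pred = (hist.val_probs[ep - 1][0] >= threshold).astype(np.uint8)
                        counts = counts + confusion(pred, masks[i])
                    per_epoch.append(metrics(counts, scope="per_experiment").as_dict())
                pooled = {
                    m: float(np.nanmean([r[m] for r in per_epoch])) for m in METRIC_NAMES
                }
                for metric, value in pooled.items():
                    records.append((e, "__pooled__", arm, metric, value))
                # per-case rows still needed for the Wilcoxon pairing
                for i, hist in enumerate(histories):
                    rec = epoch_window_mean(hist, win).as_dict()
                    for metric, value in rec.items():
                        records.append((e, case_ids[i], arm, metric, value))
            # AUC at min-validation-loss epoch, per fold
            for i, hist in enumerate(histories):
                e_star = min_loss_epoch(hist)
                auc = roc_auc(hist.val_probs[e_star - 1][0], masks[i])
                records.append((e, case_ids[i], arm, "auc", auc))

    tidy = pd.DataFrame(
        records, columns=["experiment", "case", "arm", "metric", "value"]
    )

    metric_list = list(METRIC_NAMES) + ["auc"]
    per_experiment: dict[str, pd.DataFrame] = {}
    per_case: dict[str, pd.DataFrame] = {}
    for arm in arms:
        sub = tidy[(tidy.arm == arm) & tidy.metric.isin(metric_list)]
        if pooling == "pixel_pooled":
            pooled_rows = sub[sub.case == "__pooled__"]
            auc_rows = sub[sub.metric == "auc"]
            pe = pd.concat([pooled_rows, auc_rows]).pivot_table(
                index="experiment", columns="metric", values="value", aggfunc="mean"
            )
        else:
            pe = sub.pivot_table(
                index="experiment", columns="metric", values="value", aggfunc="mean"
            )
        per_experiment[arm] = pe[metric_list]
        case_sub = sub[sub.case != "__pooled__"]
        pc = case_sub.pivot_table(
            index="case", columns="metric", values="value", aggfunc="mean"
        )
        per_case[arm] = pc.reindex(list(case_ids))[metric_list]

    welch_rows, wilcoxon_rows = [], []
    if len(arms) == 2:
        a0, a1 = arms
        for metric in metric_list:
            try:
                t, df, p = welch_t(
                    per_experiment[a0][metric].to_numpy(),
                    per_experiment[a1][metric].to_numpy(),
                )
                welch_rows.append({"metric": metric, "t": t, "df": df, "p": p})
            except ValidationError as exc:
                logger.warning("Welch %s: %s", metric, exc)
                welch_rows.append({"metric": metric, "t": np.nan, "df": np.nan, "p": np.nan})
            try:
                w, p = wilcoxon_signed_rank(
                    per_case[a0][metric].to_numpy(), per_case[a1][metric].to_numpy()
                )
                wilcoxon_rows.append({"metric": metric, "W": w, "p": p})
            except ValidationError as exc:
                logger.warning("Wilcoxon %s: %s", metric, exc)
                wilcoxon_rows.append({"metric": metric, "W": np.nan, "p": np.nan})

    return ArmComparison(
        arms=tuple(arms),
        n_experiments=n_experiments,
        case_ids=case_ids,
        per_experiment=per_experiment,
        per_case=per_case,
        welch=pd.DataFrame(welch_rows).set_index("metric") if welch_rows else None,
        wilcoxon=pd.DataFrame(wilcoxon_rows).set_index("metric") if wilcoxon_rows else None,
        records=tidy,
    )
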