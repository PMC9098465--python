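"""Leave-set-out cross-validation: SIZE, LINE, and LOC strategies.

SIZE draws random training populations of a fixed size (the validation set
is the complement) with replicated draws; LINE leaves out all plots of one
line per fold (prediction of a new line); LOC leaves out one location per
fold (prediction across environments). Accuracy is the Pearson correlation
of observed and predicted phenotypes, at plot level and on line means. For
LINE and LOC, predictions are pooled over folds — every plot is predicted
exactly once — before correlating; for SIZE, accuracy is computed per
replicate on the held-out complement and summarized as mean +/- sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernel import KernelMatrix
from .mblup import blup_predict, reml_fit
from .plsr import pls1_fit, pls1_predict, loo_tune

log = logging.getLogger(__name__)

__all__ = [
    "Fold",
    "FoldPlan",
    "CVResult",
    "make_folds",
    "run_cv",
    "accuracy_plot",
    "accuracy_line_mean",
    "summarize_replicates",
    "MBLUPPredictor",
    "PLSRPredictor",
]

STRATEGIES = ("SIZE", "LINE", "LOC")


@dataclass
class Fold:
    fold_id: str
    train_ids: list[str]
    val_ids: list[str]
    replicate: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError(f"fold {self.fold_id}: train and validation overlap")


@dataclass
class FoldPlan:
    strategy: str
    folds: list[Fold]
    seed: int | None = None
    tp_size: int | None = None


@dataclass
class CVResult:
    strategy: str
    predictor: str
    predictions: pd.DataFrame  # plot_id, line_id, fold, replicate, observed, predicted
    fold_accuracies: pd.DataFrame
    pooled_plot_accuracy: float = float("nan")
    pooled_line_mean_accuracy: float = float("nan")
    replicate_accuracies: list[float] = field(default_factory=list)
    replicate_mean: float = float("nan")
    replicate_sd: float = float("nan")
    failed_folds: list[str] = field(default_factory=list)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # derived deterministically from (base seed, replicate) so any single
    # replicate is reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def make_folds(
    strategy: str,
    meta: pd.DataFrame,
    tp_size: int | None = None,
    n_replicates: int = 1,
    seed: int = 0,
) -> FoldPlan:
    """Build the train/validation partition plan for one strategy.

    SIZE requires ``tp_size`` (< number of plots); training plots are drawn
    uniformly without replacement, once per replicate. LINE yields one fold
    per line, LOC one fold per location; in both, the validation sets
    partition the plots.
    """
    strategy = strategy.upper()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    ids = meta["plot_id"].astype(str).tolist()
    n = len(ids)
    folds: list[Fold] = []
    if strategy == "SIZE":
        if tp_size is None or not 0 < tp_size < n:
            raise ValueError(f"SIZE requires 0 < tp_size < {n}, got {tp_size}")
        for r in range(n_replicates):
            rng = _replicate_rng(seed, r)
            train = rng.choice(n, size=tp_size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[train] = True
            folds.append(
                Fold(
                    fold_id=f"size{tp_size}_rep{r}",
                    train_ids=[ids[i] for i in np.flatnonzero(mask)],
                    val_ids=[ids[i] for i in np.flatnonzero(~mask)],
                    replicate=r,
                )
            )
    elif strategy == "LINE":
        lines = sorted(meta["line_id"].astype(str).unique())
        if len(lines) < 2:
            raise ValueError("LINE requires at least 2 lines")
        by_line = meta.groupby(meta["line_id"].astype(str))["plot_id"]
        for line in lines:
            val = by_line.get_group(line).astype(str).tolist()
            if not val:
                raise ValueError(f"line {line!r} has no plots")
            folds.append(
                Fold(
                    fold_id=f"line_{line}",
                    train_ids=[p for p in ids if p not in set(val)],
                    val_ids=val,
                )
            )
    else:  # LOC
        locs = sorted(meta["location"].astype(str).unique())
        if len(locs) < 2:
            raise ValueError("LOC requires at least 2 locations")
        by_loc = meta.groupby(meta["location"].astype(str))["plot_id"]
        for loc in locs:
            val = by_loc.get_group(loc).astype(str).tolist()
            if not val:
                raise ValueError(f"location {loc!r} has no plots")
            folds.append(
                Fold(
                    fold_id=f"loc_{loc}",
                    train_ids=[p for p in ids if p not in set(val)],
                    val_ids=val,
                )
            )
    return FoldPlan(strategy=strategy, folds=folds, seed=seed, tp_size=tp_size)


def accuracy_plot(observed, predicted) -> float:
    """Pearson correlation of observed and predicted values; NaN if either
    side has zero variance."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs for an accuracy")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def accuracy_line_mean(observed, predicted, line_ids) -> float:
    """Pearson correlation between per-line averages of observed and
    predicted values; NaN with fewer than 3 distinct lines."""
    df = pd.DataFrame(
        {
            "obs": np.asarray(observed, dtype=float).ravel(),
            "pred": np.asarray(predicted, dtype=float).ravel(),
            "line": list(line_ids),
        }
    )
    means = df.groupby("line")[["obs", "pred"]].mean()
    if len(means) < 3:
        return float("nan")
    if means["obs"].std(ddof=0) == 0 or means["pred"].std(ddof=0) == 0:
        return float("nan")
    return float(np.corrcoef(means["obs"], means["pred"])[0, 1])


def summarize_replicates(accuracies) -> tuple[float, float, int]:
    """(mean, sample sd, count) across replicate accuracies; with a single
    replicate the spread is NaN."""
    a = np.asarray([x for x in accuracies if np.isfinite(x)], dtype=float)
    if a.size == 0:
        return float("nan"), float("nan"), 0
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if a.size >= 2 else float("nan")
    return mean, sd, int(a.size)


class MBLUPPredictor:
    """Kernel BLUP over folds: REML on the training block (or reused
    full-data components), then BLUP of the held-out plots."""

    def __init__(
        self,
        kernel: KernelMatrix,
        refit_per_fold: bool = True,
        vc=None,
    ) -> None:
        self.kernel = kernel
        self.refit_per_fold = refit_per_fold
        self.vc = vc
        self.name = f"MBLUP(refit={'fold' if refit_per_fold else 'full'})"

    def fit_predict(self, y: pd.Series, train_ids: list[str], val_ids: list[str]):
        y_train = y.loc[train_ids].to_numpy(dtype=float)
        if self.refit_per_fold or self.vc is None:
            tr = self.kernel.index_of(train_ids)
            sub = KernelMatrix(
                sample_ids=list(train_ids),
                M=self.kernel.M[np.ix_(tr, tr)],
                m_features=self.kernel.m_features,
                feature_mask_label=self.kernel.feature_mask_label,
            )
            vc = reml_fit(y_train, sub)
        else:
            vc = self.vc
        return blup_predict(vc, y_train, self.kernel, train_ids, val_ids)


class PLSRPredictor:
    """PLS1 over folds, either at a fixed component count or with inner
    leave-one-sample-out selection on the training set."""

    def __init__(
        self,
        Q,  # StandardizedMatrix
        n_components: int = 20,
        mode: str = "fixed",  # "fixed" | "loo"
        component_grid=(5, 10, 20, 50),
    ) -> None:
        if mode not in ("fixed", "loo"):
            raise ValueError("mode must be 'fixed' or 'loo'")
        self.Q = Q
        self.index = {p: i for i, p in enumerate(Q.plot_ids)}
        self.n_components = n_components
        self.mode = mode
        self.component_grid = tuple(component_grid)
        self.name = (
            f"PLSR({n_components} comp)" if mode == "fixed" else f"PLSR(LOO over {component_grid})"
        )

    def fit_predict(self, y: pd.Series, train_ids: list[str], val_ids: list[str]):
        tr = np.array([self.index[p] for p in train_ids])
        vl = np.array([self.index[p] for p in val_ids])
        X_train = self.Q.Q[tr]
        y_train = y.loc[train_ids].to_numpy(dtype=float)
        if self.mode == "loo":
            _, k = loo_tune(X_train, y_train, self.component_grid)
        else:
            k = self.n_components
        k = min(k, X_train.shape[0] - 1, X_train.shape[1])
        model = pls1_fit(X_train, y_train, k)
        return pls1_predict(model, self.Q.Q[vl])


def run_cv(y: pd.Series, meta: pd.DataFrame, folds: FoldPlan, predictor) -> CVResult:
    """Drive a predictor over a fold plan and score it.

    ``y`` is a phenotype Series indexed by plot_id (NaNs are dropped from
    training and excluded from scoring, with a logged count). All fitting —
    REML or PLS centering — uses training plots only. A predictor failure
    marks the fold failed and the run continues.
    """
    line_of = meta.set_index(meta["plot_id"].astype(str))["line_id"].astype(str)
    missing = y[y.isna()].index.tolist()
    if missing:
        log.info("excluding %d plot(s) with missing phenotype", len(missing))
    rows, fold_rows, failed = [], [], []
    for fold in folds.folds:
        train = [p for p in fold.train_ids if p not in missing]
        val = [p for p in fold.val_ids if p not in missing]
        if not val:
            continue
        try:
            preds = np.asarray(predictor.fit_predict(y, train, val), dtype=float)
        except Exception:
            log.exception("predictor %s failed on fold %s", predictor.name, fold.fold_id)
            failed.append(fold.fold_id)
            continue
        obs = y.loc[val].to_numpy(dtype=float)
        for p, o, pr in zip(val, obs, preds):
            rows.append(
                {
                    "plot_id": p,
                    "line_id": line_of[p],
                    "fold": fold.fold_id,
                    "replicate": fold.replicate,
                    "observed": o,
                    "predicted": pr,
                }
            )
        acc = accuracy_plot(obs, preds) if len(val) >= 3 else float("nan")
        fold_rows.append(
            {
                "fold": fold.fold_id,
                "replicate": fold.replicate,
                "n_val": len(val),
                "accuracy": acc,
            }
        )
    pred_df = pd.DataFrame(
        rows,
        columns=["plot_id", "line_id", "fold", "replicate", "observed", "predicted"],
    )
    fold_df = pd.DataFrame(fold_rows, columns=["fold", "replicate", "n_val", "accuracy"])
    result = CVResult(
        strategy=folds.strategy,
        predictor=predictor.name,
        predictions=pred_df,
        fold_accuracies=fold_df,
        failed_folds=failed,
    )
    if folds.strategy == "SIZE":
        accs = fold_df["accuracy"].tolist()
        result.replicate_accuracies = accs
        result.replicate_mean, result.replicate_sd, _ = summarize_replicates(accs)
    else:
        # pooled over folds: every plot predicted exactly once
        if len(pred_df) >= 3:
            result.pooled_plot_accuracy = accuracy_plot(
                pred_df["observed"], pred_df["predicted"]
            )
            result.pooled_line_mean_accuracy = accuracy_line_mean(
                pred_df["observed"], pred_df["predicted"], pred_df["line_id"]
            )
    return result
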