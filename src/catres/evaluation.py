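"""Evaluation protocol: subsampling, cross-validation, grid search, curves.

The training universe is built per chain by keeping every catalytic
residue and drawing six background residues per catalytic one uniformly
at random (the 6:1 rule).  Cross-validation folds split *chains*, never
residues, so windowed features of one chain cannot leak between train and
test.  Held-out scores are pooled over the folds and a single
precision-recall / ROC sweep is computed on the pool: all sites are
sorted by score and the predicted set grows one site at a time.

The reported operating point is the sweep point maximizing the F-measure
F = 2PR/(P+R).  AUPR uses the step-wise average-precision rule induced by
the one-site-at-a-time sweep; AUC uses the rank-sum (Mann-Whitney)
statistic with the half-tie correction, which equals the trapezoidal area
under the ROC sweep when scores are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import L1Logreg, TrainConfig
from .encoding import (
    CENTRAL_CHANNELS,
    CHANNEL_NAMES,
    ResidueFeatureTable,
    WindowLayout,
    WindowedDataset,
    build_dataset,
)
from .errors import ValidationError
from .types import SequenceRecord

__all__ = [
    "LAMBDA_GRID",
    "WINDOW_GRID",
    "NEGATIVE_RATIO",
    "FoldAssignment",
    "OperatingPoint",
    "EvaluationReport",
    "GridSearchResult",
    "subsample_negatives",
    "make_training_selection",
    "make_folds",
    "sweep_table",
    "pr_roc_points",
    "aupr",
    "auc",
    "auc_scores",
    "best_operating_point",
    "evaluate_scores",
    "cross_validate",
    "grid_search",
    "ablate_channel",
]

#: Default regularization grid: 0.001 to 0.020 in steps of 0.001.
LAMBDA_GRID = tuple(round(0.001 * i, 3) for i in range(1, 21))
#: Default window half-width grid.
WINDOW_GRID = tuple(range(0, 11))
#: Background residues drawn per catalytic residue.
NEGATIVE_RATIO = 6


# --------------------------------------------------------------------------
# Sampling and folds

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subsample_negatives(record: SequenceRecord, ratio: int = NEGATIVE_RATIO,
                        rng_seed=0) -> list[int]:
    """Pick background residues for one chain (0-based positions).

    Selects ``min(ratio * n_catalytic, available)`` distinct non-catalytic
    positions uniformly at random; deterministic for a fixed seed.  Chains
    without catalytic annotations contribute nothing.
    """
    if ratio < 1:
        raise ValidationError("ratio must be >= 1")
    n_cat = len(record.catalytic_positions)
    if n_cat == 0:
        return []
    rng = _as_rng(rng_seed)
    catalytic0 = {p - 1 for p in record.catalytic_positions}
    pool = np.array([i for i in range(len(record)) if i not in catalytic0])
    n_take = min(ratio * n_cat, pool.shape[0])
    chosen = rng.choice(pool, size=n_take, replace=False)
    return sorted(int(i) for i in chosen)


def make_training_selection(records: list[SequenceRecord],
                            ratio: int = NEGATIVE_RATIO,
                            seed: int = 0) -> list[tuple[str, int, int]]:
    """6:1-subsampled (chain, 0-based position, label) rows for training.

    Chains are processed in sorted id order with a single seeded stream,
    so the selection is reproducible.
    """
    rng = np.random.default_rng(seed)
    selection: list[tuple[str, int, int]] = []
    for rec in sorted(records, key=lambda r: r.chain_id):
        if not rec.catalytic_positions:
            continue
        for p in sorted(rec.catalytic_positions):
            selection.append((rec.chain_id, p - 1, +1))
        for i in subsample_negatives(rec, ratio, rng):
            selection.append((rec.chain_id, i, -1))
    return selection


@dataclass
class FoldAssignment:
    """Chain-level fold membership for k-fold cross-validation."""

    fold_of: dict[str, int]
    k: int
    seed: int

    def chains_in(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.fold_of.items() if f == fold)


def make_folds(chains: list[str], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Shuffle chains with the seed, deal round-robin into k folds."""
    chains = sorted(set(chains))
    if k > len(chains):
        raise ValidationError(
            f"cannot make {k} folds from {len(chains)} chains"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(chains))
    return FoldAssignment(
        fold_of={c: i % k for i, c in enumerate(order)}, k=k, seed=seed,
    )


# --------------------------------------------------------------------------
# Curves and summary statistics

def sweep_table(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Prefix-by-one threshold sweep over sites sorted by score.

    Ties are broken by the stable original row order.  One row per prefix
    size k = 1..N with the confusion counts and P, R, FPR, F at that
    prefix.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValidationError("labels must be +1 or -1")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    k = np.arange(1, y.shape[0] + 1)
    tp = np.cumsum(y == 1)
    fp = k - tp
    fn = n_pos - tp
    tn = n_neg - fp
    precision = tp / k
    recall = tp / n_pos
    fpr = fp / n_neg
    denom = precision + recall
    f = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame({
        "k": k, "threshold": s, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "precision": precision, "recall": recall, "fpr": fpr, "f_measure": f,
    })


def pr_roc_points(scores: np.ndarray, labels: np.ndarray,
                  ) -> tuple[list[tuple[float, float]],
                             list[tuple[float, float]]]:
    """(recall, precision) and (FPR, recall) pairs along the sweep."""
    t = sweep_table(scores, labels)
    pr = list(zip(t["recall"].tolist(), t["precision"].tolist()))
    roc = list(zip(t["fpr"].tolist(), t["recall"].tolist()))
    return pr, roc


def aupr(pr_points: list[tuple[float, float]], method: str = "step") -> float:
    """Area under the PR sweep.

    ``step`` (default) is the average-precision rule: the mean, over
    positives, of the precision at the prefix where each positive enters.
    ``trapezoid`` integrates the sorted curve instead.
    """
    if not pr_points:
        raise ValidationError("empty PR sweep")
    recalls = np.array([r for r, _ in pr_points])
    precisions = np.array([p for _, p in pr_points])
    if method == "step":
        prev = np.concatenate([[0.0], recalls[:-1]])
        rises = recalls > prev
        n_pos = int(rises.sum())
        if n_pos == 0:
            raise ValidationError("sweep contains no positives")
        return float(precisions[rises].sum() / n_pos)
    if method == "trapezoid":
        return float(np.trapezoid(precisions, recalls))
    raise ValidationError(f"unknown AUPR method {method!r}")


def auc(roc_points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under the (FPR, recall) sweep, from (0, 0)."""
    if not roc_points:
        raise ValidationError("empty ROC sweep")
    fpr = np.concatenate([[0.0], [f for f, _ in roc_points]])
    rec = np.concatenate([[0.0], [r for _, r in roc_points]])
    return float(np.trapezoid(rec, fpr))


def auc_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-sum AUC with the half-tie correction.

    Equals the fraction of (positive, negative) pairs ranked correctly,
    ties counted 1/2 — and the trapezoidal ROC area for distinct scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class OperatingPoint:
    """The maximal-F point of a sweep with its confusion counts."""

    threshold: float
    precision: float
    recall: float
    fpr: float
    f_measure: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold, "precision": self.precision,
            "recall": self.recall, "fpr": self.fpr,
            "f_measure": self.f_measure, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn,
        }


def best_operating_point(scores: np.ndarray,
                         labels: np.ndarray) -> OperatingPoint:
    """Sweep point with maximal F-measure (earliest prefix on ties)."""
    t = sweep_table(scores, labels)
    i = int(np.argmax(t["f_measure"].to_numpy()))  # argmax takes first max
    row = t.iloc[i]
    return OperatingPoint(
        threshold=float(row["threshold"]), precision=float(row["precision"]),
        recall=float(row["recall"]), fpr=float(row["fpr"]),
        f_measure=float(row["f_measure"]), tp=int(row["tp"]),
        fp=int(row["fp"]), tn=int(row["tn"]), fn=int(row["fn"]),
    )


@dataclass
class EvaluationReport:
    """Curves, areas and the maximal-F operating point for one score set."""

    pr_points: list[tuple[float, float]]
    roc_points: list[tuple[float, float]]
    aupr: float
    auc: float
    operating_point: OperatingPoint
    n: int
    n_pos: int

    def as_dict(self) -> dict:
        return {
            "aupr": self.aupr, "auc": self.auc, "n": self.n,
            "n_pos": self.n_pos,
            "operating_point": self.operating_point.as_dict(),
            "pr_points": [list(p) for p in self.pr_points],
            "roc_points": [list(p) for p in self.roc_points],
        }


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> EvaluationReport:
    """Full sweep evaluation of one pooled score vector."""
    pr, roc = pr_roc_points(scores, labels)
    return EvaluationReport(
        pr_points=pr, roc_points=roc, aupr=aupr(pr),
        auc=auc_scores(scores, labels),
        operating_point=best_operating_point(scores, labels),
        n=len(labels), n_pos=int(np.sum(np.asarray(labels) == 1)),
    )


# --------------------------------------------------------------------------
# Cross-validation and grid search

def cross_validate(dataset: WindowedDataset, folds: FoldAssignment,
                   lam: float, config: TrainConfig | None = None,
                   ) -> tuple[np.ndarray, EvaluationReport]:
    """Chain-level k-fold CV: pooled held-out scores plus their report.

    Each fold trains on the other folds' chains and scores its own; the
    held-out scores are pooled (in original row order) before a single
    sweep is evaluated.
    """
    groups = np.asarray([str(g) for g in dataset.groups], dtype=object)
    fold_idx = np.array([folds.fold_of.get(g, -1) for g in groups])
    if np.any(fold_idx < 0):
        missing = sorted(set(groups[fold_idx < 0]))
        raise ValidationError(f"chains without fold assignment: {missing}")
    pooled = np.empty(len(dataset))
    for f in range(folds.k):
        test_mask = fold_idx == f
        train_mask = ~test_mask
        if not np.any(test_mask):
            continue
        y_train = dataset.y[train_mask]
        if len(set(y_train.tolist())) < 2:
            raise ValidationError(
                f"fold {f}: training split contains a single class"
            )
        results = L1Logreg(dataset.X[train_mask], y_train,
                           layout=dataset.layout).fit(lam, config)
        pooled[test_mask] = results.predict(dataset.X[test_mask])
    return pooled, evaluate_scores(pooled, dataset.y)


@dataclass
class GridSearchResult:
    """Grid-search table plus the AUPR-optimal cell."""

    table: pd.DataFrame  # columns: window_size, lambda, aupr, auc
    best_window: int
    best_lambda: float

    def best(self) -> tuple[int, float]:
        return self.best_window, self.best_lambda


def grid_search(tables: dict[str, ResidueFeatureTable],
                selected: list[tuple[str, int, int]],
                lambdas=LAMBDA_GRID, windows=WINDOW_GRID,
                k: int = 10, seed: int = 0,
                config: TrainConfig | None = None,
                channels: tuple[str, ...] = CHANNEL_NAMES,
                progress=None) -> GridSearchResult:
    """Evaluate CV at every (window, lambda) cell; pick maximal AUPR.

    Ties prefer the smaller window, then the smaller lambda.  The fold
    assignment is fixed across the grid (same chains, same seed).
    """
    lambdas = list(lambdas)
    windows = list(windows)
    if not lambdas or not windows:
        raise ValidationError("empty grid")
    chains = sorted({chain for chain, _, _ in selected})
    folds = make_folds(chains, k=k, seed=seed)
    rows = []
    for w in windows:
        layout = WindowLayout(window_size=w, channels=channels)
        dataset = build_dataset(tables, selected, layout)
        for lam in lambdas:
            _, report = cross_validate(dataset, folds, lam, config)
            rows.append({"window_size": w, "lambda": lam,
                         "aupr": report.aupr, "auc": report.auc})
            if progress is not None:
                progress(rows[-1])
    table = pd.DataFrame(rows)
    # max AUPR; ties -> smaller window, then smaller lambda
    best = min(
        rows, key=lambda r: (-r["aupr"], r["window_size"], r["lambda"]))
    return GridSearchResult(table=table, best_window=int(best["window_size"]),
                            best_lambda=float(best["lambda"]))


def ablate_channel(tables: dict[str, ResidueFeatureTable],
                   selected: list[tuple[str, int, int]],
                   channel_name: str, window: int, lam: float,
                   k: int = 10, seed: int = 0,
                   config: TrainConfig | None = None) -> EvaluationReport:
    """Leave-one-attribute-out: drop a channel's slots and rerun CV."""
    if channel_name not in CHANNEL_NAMES:
        raise ValidationError(
            f"unknown channel {channel_name!r}; expected one of "
            f"{CHANNEL_NAMES}"
        )
    kept = tuple(c for c in CHANNEL_NAMES if c != channel_name)
    layout = WindowLayout(window_size=window, channels=kept)
    dataset = build_dataset(tables, selected, layout)
    chains = sorted({chain for chain, _, _ in selected})
    folds = make_folds(chains, k=k, seed=seed)
    _, report = cross_validate(dataset, folds, lam, config)
    return report


# --------------------------------------------------------------------------
# Exports

def write_report_json(report: EvaluationReport, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=1)
        fh.write("\n")


def write_curves_tsv(report: EvaluationReport, pr_path, roc_path) -> None:
    with open(pr_path, "w") as fh:
        fh.write("recall\tprecision\n")
        for r, p in report.pr_points:
            fh.write(f"{r!r}\t{p!r}\n")
    with open(roc_path, "w") as fh:
        fh.write("fpr\trecall\n")
        for f, r in report.roc_points:
            fh.write(f"{f!r}\t{r!r}\n")


def write_grid_tsv(result: GridSearchResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)
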