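"""Feature ranking (Fisher-Markov style) and incremental feature selection.

Ranking uses the linear-kernel Fisher-Markov criterion: for feature k with
class means mu_ck, overall mean mu_k and class sizes n_c,

    score_k = (1/n) * sum_c n_c * (mu_ck - mu_k)^2  -  gamma * (1/n) * sum_i x_ik^2

i.e. the between-class variance of the feature penalised by gamma times its
second moment.  With the default gamma = 0 this reduces to a Fisher-score-like
between-class separation; all features here live on comparable [-1, 1]
scales, so no per-feature variance normalisation is applied.  Ties keep the
original column order, making the ranking deterministic.

Incremental feature selection (IFS) then evaluates growing prefixes of the
ranking (sizes step, 2*step, ... and finally the full set), scoring each by
pooled cross-validated MCC through a caller-supplied evaluation callback,
and keeps the best prefix (ties: higher AUC, then the smaller subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .encoding import FeatureMatrix

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class RankedFeatures:
    names: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.scores):
            raise SelectionError("names/scores length mismatch")
        if len(set(self.names)) != len(self.names):
            raise SelectionError("duplicate feature names in ranking")
        if any(a > b for a, b in zip(self.scores[1:], self.scores[:-1])):
            # defensive: scores must be non-increasing
            raise SelectionError("ranking scores are not sorted")

    def prefix(self, size: int) -> list[str]:
        return self.names[:size]


def fisher_markov_scores(X: np.ndarray, y: np.ndarray,
                         gamma: float = 0.0) -> np.ndarray:
    """Per-feature linear-kernel Fisher-Markov relevance scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise SelectionError("need two classes to rank features")
    n = len(y)
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    for c in classes:
        mask = y == c
        if mask.sum() < 2:
            raise SelectionError(f"class {c!r} has fewer than 2 samples")
        between += mask.sum() * (X[mask].mean(axis=0) - mu) ** 2
    between /= n
    return between - gamma * (X ** 2).mean(axis=0)


def rank_features(fm: FeatureMatrix, y: np.ndarray | None = None,
                  gamma: float = 0.0) -> RankedFeatures:
    """Rank features by relevance score, descending; ties keep column order."""
    if y is None:
        y = fm.y()
    scores = fisher_markov_scores(fm.X.to_numpy(), y, gamma=gamma)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return RankedFeatures(names=[fm.X.columns[i] for i in order],
                          scores=[float(scores[i]) for i in order])


@dataclass
class IFSResult:
    step_size: int
    evaluated_sizes: list[int]
    reports: dict[int, object]          # size -> EvalReport
    optimal_size: int
    optimal_features: list[str]


def incremental_search(fm: FeatureMatrix, ranking: RankedFeatures,
                       evaluator: Callable[[FeatureMatrix], object],
                       step: int = 5) -> IFSResult:
    """Evaluate ranking prefixes of sizes step, 2*step, ... and the full set.

    ``evaluator`` receives the restricted feature matrix and must return an
    object with ``mcc`` and ``auc`` attributes (an EvalReport from 5-fold
    cross-validation).  The optimal size maximises MCC; ties prefer higher
    AUC, then the smaller subset.  The chosen subset is always a prefix of
    the ranking.
    """
    if step < 1:
        raise SelectionError(f"step must be >= 1, got {step}")
    total = len(ranking.names)
    sizes = list(range(step, total + 1, step))
    if not sizes or sizes[-1] != total:
        sizes.append(total)
    reports: dict[int, object] = {}
    for size in sizes:
        sub = fm.select(ranking.prefix(size))
        try:
            reports[size] = evaluator(sub)
        except Exception as exc:
            raise SelectionError(
                f"evaluation failed at subset size {size}: {exc}"
            ) from exc
    best = max(sizes, key=lambda s: (reports[s].mcc, reports[s].auc, -s))
    return IFSResult(step_size=step, evaluated_sizes=sizes, reports=reports,
                     optimal_size=best,
                     optimal_features=ranking.prefix(best))


def write_ranking(ranking: RankedFeatures, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tscore\trank\n")
        for i, (name, score) in enumerate(zip(ranking.names, ranking.scores), 1):
            fh.write(f"{name}\t{score:.10g}\t{i}\n")


def write_ifs_report(result: IFSResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("size\tsensitivity\tspecificity\taccuracy\tmcc\tauc\n")
        for size in result.evaluated_sizes:
            r = result.reports[size]
            fh.write(f"{size}\t{r.sensitivity:.4f}\t{r.specificity:.4f}\t"
                     f"{r.accuracy:.4f}\t{r.mcc:.4f}\t{r.auc:.4f}\n")
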