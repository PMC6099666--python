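"""RBF-SVM training, cross-validation, evaluation metrics, and model bundles.

Classifiers are support vector machines with a radial basis function kernel;
the (C, gamma) pair is chosen by exhaustive grid search over
C in 2^-5 .. 2^15 and gamma in 2^-15 .. 2^3 (powers of 4 by default) with
inner stratified 5-fold cross-validated accuracy, then the model is refit on
all training data with sigmoid (Platt) calibration of decision values into
probabilities.

Evaluation follows the pooled-prediction convention: a stratified k-fold
split is fixed once per run (seeded); the held-out predictions of all folds
are combined into a single confusion matrix from which sensitivity,
specificity, accuracy and the Matthews correlation coefficient are computed,
and a single ROC/AUC is computed from the pooled probabilities.

A :class:`ModelBundle` packages everything needed to reproduce predictions:
species tag, the motif list the encoder was built with, the ordered selected
feature names, hyperparameters, the fitted classifier, and provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn import metrics as skmetrics
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .encoding import (FeatureMatrix, PCPIndexTable, encode_dataset,
                       load_pcp_table)
from .motif_mining import MotifPattern, read_motif_table, write_motif_table
from .sequences import Dataset

logger = logging.getLogger(__name__)

#: LIBSVM-conventional grid, powers of 4.
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))

#: Coarse grid used inside iterated searches (IFS, repeated-seed studies)
#: where the full grid would be re-run dozens of times.
FAST_C_GRID = (0.5, 8.0, 128.0)
FAST_GAMMA_GRID = (2.0 ** -7, 2.0 ** -3, 2.0)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion counts, derived rates, and ROC/AUC of one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy, "mcc": self.mcc, "auc": self.auc}


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    """Sensitivity, specificity, accuracy, MCC from a confusion matrix.

    Sens = TP/(TP+FN); Spec = TN/(TN+FP); Acc = (TP+TN)/total;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP)),
    defined as 0 when any marginal is zero.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ModelError("negative confusion counts")
    total = tp + tn + fp + fn
    if total == 0:
        raise ModelError("empty confusion matrix")
    if tp + fn == 0 or tn + fp == 0:
        raise ModelError("a class is absent; sensitivity/specificity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / total
    denom = math.sqrt(float(tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens,
                      specificity=spec, accuracy=acc, mcc=mcc)


def roc_auc(scores: Sequence[float], y: Sequence[float]
            ) -> tuple[list[tuple[float, float]], float]:
    """Threshold-swept ROC points and trapezoidal AUC.

    AUC equals the probability that a random positive outscores a random
    negative, counting ties one half.  Labels are +1/-1 (anything > 0 is
    treated as positive).
    """
    y = np.asarray(y, dtype=float) > 0
    scores = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ModelError("both classes must be present for ROC/AUC")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def report_from_predictions(y: np.ndarray, prob: np.ndarray,
                            threshold: float = 0.5) -> EvalReport:
    """Pooled EvalReport from true labels (+1/-1) and probabilities."""
    y = np.asarray(y, dtype=float)
    pred = np.where(np.asarray(prob) >= threshold, 1.0, -1.0)
    tp = int(np.sum((y > 0) & (pred > 0)))
    tn = int(np.sum((y < 0) & (pred < 0)))
    fp = int(np.sum((y < 0) & (pred > 0)))
    fn = int(np.sum((y > 0) & (pred < 0)))
    report = metrics_from_counts(tp, tn, fp, fn)
    report.roc, report.auc = roc_auc(prob, y)
    return report


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained species model plus everything needed to reuse it."""

    species: str
    motifs: list[MotifPattern]
    selected_features: list[str]
    hyperparams: dict                    # {"C": float, "gamma": float}
    classifier: SVC
    pcp_mode: str = "mean_sd"
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, outdir / "classifier.joblib")
        write_motif_table(self.motifs, outdir / "motifs.tsv")
        payload_sha = hashlib.sha256(
            (outdir / "classifier.joblib").read_bytes()).hexdigest()
        meta = {"species": self.species,
                "selected_features": self.selected_features,
                "hyperparams": self.hyperparams,
                "pcp_mode": self.pcp_mode,
                "seed": self.seed,
                "classifier_sha256": payload_sha,
                "provenance": self.provenance}
        (outdir / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "ModelBundle":
        outdir = Path(outdir)
        meta = json.loads((outdir / "bundle.json").read_text())
        payload = (outdir / "classifier.joblib").read_bytes()
        if hashlib.sha256(payload).hexdigest() != meta["classifier_sha256"]:
            raise ModelError("classifier payload checksum mismatch")
        return cls(species=meta["species"],
                   motifs=read_motif_table(outdir / "motifs.tsv"),
                   selected_features=meta["selected_features"],
                   hyperparams=meta["hyperparams"],
                   classifier=joblib.load(outdir / "classifier.joblib"),
                   pcp_mode=meta["pcp_mode"], seed=meta["seed"],
                   provenance=meta.get("provenance", {}))


def grid_search_svm(X: np.ndarray, y: np.ndarray, seed: int = 0,
                    c_grid: Sequence[float] = DEFAULT_C_GRID,
                    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                    inner_folds: int = 5) -> tuple[float, float]:
    """Exhaustive (C, gamma) search by inner stratified CV accuracy."""
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(SVC(kernel="rbf"),
                      {"C": list(c_grid), "gamma": list(gamma_grid)},
                      scoring="accuracy", cv=cv, n_jobs=1)
    gs.fit(X, y)
    return float(gs.best_params_["C"]), float(gs.best_params_["gamma"])


def fit_svc(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
            seed: int = 0):
    """Fit an RBF SVC with sigmoid (Platt) calibration of decision values.

    The final SVC is refit on all the data; the sigmoid is fitted on
    cross-validated decision values (ensemble=False), so probabilities are
    deterministic given the inputs.
    """
    clf = CalibratedClassifierCV(SVC(kernel="rbf", C=C, gamma=gamma),
                                 method="sigmoid", cv=5, ensemble=False)
    clf.fit(X, y)
    return clf


def positive_probability(clf, X: np.ndarray) -> np.ndarray:
    """Calibrated probability of the positive (+1) class."""
    pos_col = int(np.where(clf.classes_ > 0)[0][0])
    return clf.predict_proba(X)[:, pos_col]


def decision_scores(clf, X: np.ndarray) -> np.ndarray:
    """Raw SVM decision values of the underlying (calibrated) classifier."""
    return clf.calibrated_classifiers_[0].estimator.decision_function(X)


def train_svm(fm: FeatureMatrix, motifs: Sequence[MotifPattern],
              selected_features: Sequence[str] | None = None,
              species: str = "U", seed: int = 0,
              c_grid: Sequence[float] = DEFAULT_C_GRID,
              gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
              pcp_mode: str = "mean_sd") -> ModelBundle:
    """Grid-search, fit and package a final model on all training data."""
    names = list(selected_features) if selected_features else list(fm.X.columns)
    sub = fm.select(names)
    y = sub.y()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ModelError("training data has a single class")
    if counts.min() < 10:
        raise ModelError(
            f"need >= 10 samples per class to train, have {counts.min()}")
    X = sub.X.to_numpy()
    C, gamma = grid_search_svm(X, y, seed=seed, c_grid=c_grid,
                               gamma_grid=gamma_grid)
    clf = fit_svc(X, y, C, gamma, seed=seed)
    prov = {"seed": seed,
            "n_pos": int(counts[classes > 0][0]) if (classes > 0).any() else 0,
            "n_neg": int(counts[classes < 0][0]) if (classes < 0).any() else 0,
            "data_sha256": hashlib.sha256(
                np.ascontiguousarray(X).tobytes()).hexdigest()}
    return ModelBundle(species=species, motifs=list(motifs),
                       selected_features=names,
                       hyperparams={"C": C, "gamma": gamma},
                       classifier=clf, pcp_mode=pcp_mode, seed=seed,
                       provenance=prov)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def fold_assignment(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold labels (0..k-1), deterministic given the seed."""
    y = np.asarray(y)
    for c in np.unique(y):
        if (y == c).sum() < k:
            raise ModelError(f"class {c!r} has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def cross_validate(fm: FeatureMatrix, k: int = 5, seed: int = 0,
                   c_grid: Sequence[float] = FAST_C_GRID,
                   gamma_grid: Sequence[float] = FAST_GAMMA_GRID,
                   folds: np.ndarray | None = None,
                   hyperparams: tuple[float, float] | None = None
                   ) -> EvalReport:
    """Stratified k-fold CV with pooled held-out predictions.

    Every sample is predicted exactly once; the pooled predictions give one
    confusion matrix and one ROC.  With ``hyperparams`` given, (C, gamma) are
    fixed and only refit per fold; otherwise each fold runs its own grid
    search on the training part.
    """
    if k < 2:
        raise ModelError(f"k must be >= 2, got {k}")
    y = fm.y()
    X = fm.X.to_numpy()
    if folds is None:
        folds = fold_assignment(y, k, seed)
    prob = np.empty(len(y))
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        if len(np.unique(y[tr])) < 2:
            raise ModelError(f"fold {f} leaves a single-class training set")
        if hyperparams is None:
            C, gamma = grid_search_svm(X[tr], y[tr], seed=seed,
                                       c_grid=c_grid, gamma_grid=gamma_grid)
        else:
            C, gamma = hyperparams
        clf = fit_svc(X[tr], y[tr], C, gamma, seed=seed)
        prob[te] = positive_probability(clf, X[te])
    return report_from_predictions(y, prob)


def nested_cross_validate(ds: Dataset, k: int = 5, seed: int = 0,
                          k_motifs: int = 20, min_support: float = 0.02,
                          c_grid: Sequence[float] = FAST_C_GRID,
                          gamma_grid: Sequence[float] = FAST_GAMMA_GRID,
                          table: PCPIndexTable | None = None) -> EvalReport:
    """Selection-bias-free CV: motif mining is repeated inside every fold.

    Motif mining is part of model fitting — the top-RDI patterns are chosen
    from thousands of candidates — so mining on data that later serves as a
    held-out fold leaks information and inflates apparent accuracy (visibly
    so on signal-free data).  Here each fold mines its own motifs on its
    training part only, encodes both parts with them, grid-searches and
    fits, and predicts the held-out part; predictions are pooled as usual.
    """
    if table is None:
        table = load_pcp_table()
    y = np.array([1.0 if r.is_positive else -1.0 for r in ds])
    folds = fold_assignment(y, k, seed)
    prob = np.empty(len(y))
    recs = ds.records
    from .motif_mining import mine_top_motifs
    for f in np.unique(folds):
        tr_idx = np.where(folds != f)[0]
        te_idx = np.where(folds == f)[0]
        train = Dataset([recs[i] for i in tr_idx])
        test = Dataset([recs[i] for i in te_idx])
        motifs = mine_top_motifs(train.positives(), train.negatives(),
                                 k=k_motifs, min_support=min_support)
        fm_tr = encode_dataset(train, motifs, table)
        fm_te = encode_dataset(test, motifs, table)
        C, gamma = grid_search_svm(fm_tr.X.to_numpy(), fm_tr.y(), seed=seed,
                                   c_grid=c_grid, gamma_grid=gamma_grid)
        clf = fit_svc(fm_tr.X.to_numpy(), fm_tr.y(), C, gamma, seed=seed)
        prob[te_idx] = positive_probability(clf, fm_te.X.to_numpy())
    return report_from_predictions(y, prob)


# ---------------------------------------------------------------------------
# Prediction and probability binning
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    id: str
    score: float
    probability: float
    label: str  # "SP" / "nonSP" at threshold 0.5


def predict(bundle: ModelBundle, ds: Dataset,
            table: PCPIndexTable | None = None
            ) -> tuple[list[Prediction], list[str]]:
    """Score records with a trained bundle; unencodable records are reported.

    Records are encoded with the bundle's own motif list and restricted to
    its selected features; the probability is the calibrated chance of being
    secreted.
    """
    if table is None:
        table = load_pcp_table()
    fm = encode_dataset(ds, bundle.motifs, table, pcp_mode=bundle.pcp_mode)
    X = fm.X[bundle.selected_features].to_numpy()
    clf = bundle.classifier
    probs = positive_probability(clf, X)
    scores = decision_scores(clf, X)
    preds = [Prediction(id=rid, score=float(s), probability=float(p),
                        label="SP" if p >= 0.5 else "nonSP")
             for rid, s, p in zip(fm.X.index, scores, probs)]
    return preds, fm.failures


@dataclass
class ProbabilityBins:
    """Decile histogram of predicted secretion probabilities."""

    edges: list[float]            # 0.0, 0.1, ..., 1.0
    counts: list[int]
    percentages: list[float]      # of total, rounded to 2 decimals

    @property
    def total(self) -> int:
        return sum(self.counts)


def bin_probabilities(probabilities: Sequence[float]) -> ProbabilityBins:
    """Ten decile bins [lo, hi), the last closed at 100%."""
    probs = np.asarray(list(probabilities), dtype=float)
    if probs.size == 0:
        raise ModelError("no predictions to bin")
    edges = [i / 10 for i in range(11)]
    idx = np.minimum((probs * 10).astype(int), 9)
    counts = [int(np.sum(idx == i)) for i in range(10)]
    total = probs.size
    pct = [round(100.0 * c / total, 2) for c in counts]
    return ProbabilityBins(edges=edges, counts=counts, percentages=pct)


# ---------------------------------------------------------------------------
# Species-specific vs universal scheme comparison
# ---------------------------------------------------------------------------

@dataclass
class SchemeModel:
    """One scheme's feature construction: motifs, subset, hyperparameters."""

    tag: str
    motifs: list[MotifPattern]
    selected_features: list[str]
    hyperparams: tuple[float, float]
    features: FeatureMatrix           # the model's own data, fully encoded


def _build_scheme_model(data: Dataset, tag: str, seed: int,
                        table: PCPIndexTable, k_motifs: int,
                        min_support: float, step: int, k: int,
                        c_grid: Sequence[float],
                        gamma_grid: Sequence[float]) -> SchemeModel:
    """Mine motifs, encode, rank and IFS-select on one scheme's own data.

    Hyperparameters are grid-searched once on the full feature set and held
    fixed through the incremental search (paired comparisons across subset
    sizes), which keeps repeated-seed studies tractable.
    """
    from .motif_mining import mine_top_motifs
    from .selection import incremental_search, rank_features

    motifs = mine_top_motifs(data.positives(), data.negatives(), k=k_motifs,
                             min_support=min_support)
    fm = encode_dataset(data, motifs, table)
    y = fm.y()
    hp = grid_search_svm(fm.X.to_numpy(), y, seed=seed,
                         c_grid=c_grid, gamma_grid=gamma_grid)
    folds = fold_assignment(y, k, seed)
    ranking = rank_features(fm)
    ifs = incremental_search(
        fm, ranking,
        evaluator=lambda sub: cross_validate(sub, k=k, seed=seed,
                                             folds=folds, hyperparams=hp),
        step=step)
    return SchemeModel(tag=tag, motifs=motifs,
                       selected_features=ifs.optimal_features,
                       hyperparams=hp, features=fm)


def compare_schemes(ds: Dataset, seed: int = 0, k_motifs: int = 20,
                    min_support: float = 0.05, step: int = 10, k: int = 5,
                    c_grid: Sequence[float] = FAST_C_GRID,
                    gamma_grid: Sequence[float] = FAST_GAMMA_GRID,
                    table: PCPIndexTable | None = None
                    ) -> dict[str, dict[str, EvalReport]]:
    """Paired evaluation of per-species models against one pooled model.

    The universal model mines its motifs and selects its feature subset on
    the pooled data; each species model does the same on its species' data
    alone.  Evaluation is paired: for every species one stratified fold
    assignment is fixed and both schemes predict exactly the same held-out
    proteins — the species model trains on the species' remaining folds, the
    universal model on everything outside the held-out fold.

    Returns ``{species: {"specific": EvalReport, "universal": EvalReport}}``.
    Species with fewer than ``k`` members per class (or too few to mine and
    train) are excluded with a warning.
    """
    if table is None:
        table = load_pcp_table()
    species = sorted({r.species for r in ds if r.species})
    if len(species) < 1:
        raise ModelError("no species tags in the dataset")
    universal = _build_scheme_model(ds, "U", seed, table, k_motifs,
                                    min_support, step, k, c_grid, gamma_grid)
    results: dict[str, dict[str, EvalReport]] = {}
    for sp in species:
        sub = ds.subset_species(sp)
        if sub.num_pos < 2 * k or sub.num_neg < 2 * k:
            logger.warning("species %s has too little data; skipped", sp)
            continue
        spec = _build_scheme_model(sub, sp, seed, table, k_motifs,
                                   min_support, step, k, c_grid, gamma_grid)
        y_sp = spec.features.y()
        folds = fold_assignment(y_sp, k, seed)
        sp_ids = list(spec.features.X.index)
        prob_spec = np.empty(len(y_sp))
        prob_univ = np.empty(len(y_sp))
        # universal view of the species data, encoded with universal motifs
        univ_all = universal.features.select(universal.selected_features)
        univ_sp_rows = univ_all.X.loc[sp_ids]
        spec_X = spec.features.X[spec.selected_features]
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            held_ids = set(np.asarray(sp_ids)[te])
            clf_s = fit_svc(spec_X.to_numpy()[tr], y_sp[tr],
                            *spec.hyperparams, seed=seed)
            prob_spec[te] = positive_probability(clf_s,
                                                  spec_X.to_numpy()[te])
            keep = ~univ_all.X.index.isin(held_ids)
            clf_u = fit_svc(univ_all.X.to_numpy()[keep],
                            univ_all.y()[keep], *universal.hyperparams,
                            seed=seed)
            prob_univ[te] = positive_probability(
                clf_u, univ_sp_rows.to_numpy()[te])
        results[sp] = {
            "specific": report_from_predictions(y_sp, prob_spec),
            "universal": report_from_predictions(y_sp, prob_univ),
        }
    return results


def write_scheme_comparison(results: dict[str, dict[str, EvalReport]],
                            path: str | Path) -> None:
    """Per-species paired table (scheme, sensitivity, specificity, accuracy, MCC, AUC)."""
    with open(path, "w") as fh:
        fh.write("species\tscheme\tsensitivity\tspecificity\taccuracy\tmcc\tauc\n")
        for sp in sorted(results):
            for scheme in ("specific", "universal"):
                r = results[sp][scheme]
                fh.write(f"{sp}\t{scheme}\t{r.sensitivity:.4f}\t"
                         f"{r.specificity:.4f}\t{r.accuracy:.4f}\t"
                         f"{r.mcc:.4f}\t{r.auc:.4f}\n")


def write_predictions(preds: Sequence[Prediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tscore\tprobability\tpredicted_label\n")
        for p in preds:
            fh.write(f"{p.id}\t{p.score:.6g}\t{p.probability:.6g}\t{p.label}\n")
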