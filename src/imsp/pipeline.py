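"""End-to-end workflow: split -> mine -> encode -> rank -> IFS -> train -> evaluate.

The run is driven by a :class:`RunConfig` (loadable from YAML); every
intermediate artifact is written into the output directory together with a
run log recording the seed, package versions and artifact checksums, so a
re-run with the same config and seed reproduces the artifacts byte for byte.

Hyperparameters are grid-searched once on the full 60-feature training
matrix with the coarse grid and held fixed through the incremental feature
search (one fold assignment per run, so subset comparisons are paired);
the final model is then grid-searched on the selected subset with the
configured (by default full) grid and refit on all training data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .encoding import encode_dataset, load_pcp_table, write_feature_matrix
from .model_eval import (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, FAST_C_GRID,
                         FAST_GAMMA_GRID, EvalReport, cross_validate,
                         fold_assignment, grid_search_svm, predict,
                         report_from_predictions, train_svm,
                         write_predictions)
from .motif_mining import mine_top_motifs, write_motif_table
from .selection import (incremental_search, rank_features, write_ifs_report,
                        write_ranking)
from .sequences import (Dataset, read_fasta, read_label_table, split_dataset,
                        write_fasta, write_split_manifest)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Source of truth for one pipeline run; CLI flags override YAML fields."""

    fasta: str | None = None
    labels: str | None = None
    seed: int = 0
    species: str = "U"
    train_fraction: float = 4 / 5
    k_motifs: int = 20
    min_support: float = 0.05
    step_size: int = 5
    pcp_mode: str = "mean_sd"
    fms_gamma: float = 0.0
    cv_folds: int = 5
    final_c_grid: list[float] = field(default_factory=lambda: list(DEFAULT_C_GRID))
    final_gamma_grid: list[float] = field(default_factory=lambda: list(DEFAULT_GAMMA_GRID))
    search_c_grid: list[float] = field(default_factory=lambda: list(FAST_C_GRID))
    search_gamma_grid: list[float] = field(default_factory=lambda: list(FAST_GAMMA_GRID))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    cv_report: EvalReport
    test_report: EvalReport | None
    optimal_size: int
    optimal_features: list[str]
    motifs: list
    bundle_dir: Path


def run_pipeline(config: RunConfig, outdir: str | Path,
                 dataset: Dataset | None = None) -> PipelineResult:
    """Execute the full workflow and write every intermediate artifact.

    ``dataset`` may be passed directly (e.g. a synthetic benchmark); else it
    is read from ``config.fasta``/``config.labels``.  On failure the raised
    :class:`PipelineError` names the stage; artifacts written so far remain.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage = "load"
    try:
        if dataset is None:
            if not config.fasta:
                raise ValueError("config field 'fasta' is required")
            label_map = (read_label_table(config.labels)
                         if config.labels else None)
            dataset, rejected = read_fasta(config.fasta, label_map)
            if rejected:
                (outdir / "rejected_records.txt").write_text(
                    "\n".join(rejected) + "\n")

        stage = "split"
        split = split_dataset(dataset, config.train_fraction, seed=config.seed)
        write_fasta(split.train, outdir / "train.fasta")
        write_fasta(split.test, outdir / "test.fasta")
        write_split_manifest(split, outdir / "split_manifest.tsv")

        stage = "mine"
        motifs = mine_top_motifs(split.train.positives(),
                                 split.train.negatives(),
                                 k=config.k_motifs,
                                 min_support=config.min_support)
        if not motifs:
            raise ValueError("no candidate motifs passed the support filter; "
                             "lower min_support")
        write_motif_table(motifs, outdir / "motifs.tsv")

        stage = "encode"
        table = load_pcp_table()
        fm = encode_dataset(split.train, motifs, table,
                            pcp_mode=config.pcp_mode)
        write_feature_matrix(fm, outdir / "features.tsv")

        stage = "rank"
        ranking = rank_features(fm, gamma=config.fms_gamma)
        write_ranking(ranking, outdir / "ranking.tsv")

        stage = "ifs"
        y = fm.y()
        folds = fold_assignment(y, config.cv_folds, config.seed)
        search_hp = grid_search_svm(fm.X.to_numpy(), y, seed=config.seed,
                                    c_grid=config.search_c_grid,
                                    gamma_grid=config.search_gamma_grid)
        ifs = incremental_search(
            fm, ranking,
            evaluator=lambda sub: cross_validate(
                sub, k=config.cv_folds, seed=config.seed, folds=folds,
                hyperparams=search_hp),
            step=config.step_size)
        write_ifs_report(ifs, outdir / "ifs_report.tsv")
        cv_report = ifs.reports[ifs.optimal_size]

        stage = "train"
        bundle = train_svm(fm, motifs,
                           selected_features=ifs.optimal_features,
                           species=config.species, seed=config.seed,
                           c_grid=config.final_c_grid,
                           gamma_grid=config.final_gamma_grid,
                           pcp_mode=config.pcp_mode)
        bundle_dir = outdir / "model"
        bundle.save(bundle_dir)

        stage = "evaluate"
        test_report = None
        if split.test.num_pos >= 1 and split.test.num_neg >= 1:
            preds, _ = predict(bundle, split.test, table)
            write_predictions(preds, outdir / "test_predictions.tsv")
            by_id = {r.id: r for r in split.test}
            y_test = np.array([1.0 if by_id[p.id].is_positive else -1.0
                               for p in preds])
            test_report = report_from_predictions(
                y_test, np.array([p.probability for p in preds]))
        _write_eval(outdir / "eval_report.json", cv_report, test_report)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    _write_run_log(outdir, config)
    return PipelineResult(outdir=outdir, cv_report=cv_report,
                          test_report=test_report,
                          optimal_size=ifs.optimal_size,
                          optimal_features=ifs.optimal_features,
                          motifs=motifs, bundle_dir=bundle_dir)


def _write_eval(path: Path, cv: EvalReport, test: EvalReport | None) -> None:
    out = {"cross_validation": cv.as_dict()}
    if test is not None:
        out["independent_test"] = test.as_dict()
    path.write_text(json.dumps(out, indent=2))


def _write_run_log(outdir: Path, config: RunConfig) -> None:
    import sklearn
    artifacts = sorted(p for p in outdir.rglob("*")
                       if p.is_file() and p.name != "run.json")
    log = {
        "imsp_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
        "seed": config.seed,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p)
                      for p in artifacts},
    }
    (outdir / "run.json").write_text(json.dumps(log, indent=2))
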