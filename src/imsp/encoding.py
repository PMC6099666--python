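"""Feature encoders: amino-acid composition, motif presence, physicochemical profile.

Each protein becomes a 60-dimensional named vector:

* ``aac_A .. aac_Y`` — the 20 residue frequencies, min-max normalised to
  [-1, 1] within the record's own frequency vector,
* ``mtf_1 .. mtf_20`` — presence (+1) / absence (-1) of each mined motif,
* ``pcp_mean_1..10, pcp_sd_1..10`` — per-property mean and population
  standard deviation of a 10-property residue index profile, min-max
  normalised within the record's 20-element vector.

Ambiguity codes (X, B, Z, U, O, J) are excluded from composition
denominators and property profiles, and never match motifs.

The 10-property index table ships with the package
(``data/pcp_index.csv``, sha256 recorded below).  Values are compiled from
the published amino-acid index literature for: hydrophobicity, polarity,
solvation free energy, graph shape index, transfer free energy, correlation
coefficient in regression analysis, residue accessible surface area,
partition coefficient, entropy of formulation and protein kinase A.  Each
property is kept on its native scale; the per-record normalisation removes
scale differences.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .motif_mining import MotifPattern, pattern_regex
from .sequences import Dataset, ProteinRecord, STANDARD_AA

logger = logging.getLogger(__name__)

PCP_INDEX_SHA256 = "234875f5972200b951a91f424fd866e9f019bed5a18b199874712c0639a7b342"

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


class EncodingError(ValueError):
    pass


@dataclass
class PCPIndexTable:
    """10 properties x 20 residues index matrix, residues in ``STANDARD_AA`` order."""

    values: np.ndarray
    property_names: list[str]
    residue_order: str = STANDARD_AA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.property_names), 20):
            raise EncodingError(
                f"index table shape {self.values.shape} does not match "
                f"{len(self.property_names)} properties x 20 residues")
        if not np.all(np.isfinite(self.values)):
            raise EncodingError("index table contains non-finite values")

    def column(self, residue: str) -> np.ndarray:
        return self.values[:, _AA_INDEX[residue]]


def load_pcp_table(path: str | Path | None = None, verify: bool = True
                   ) -> PCPIndexTable:
    """Load the shipped (or a user-supplied) property index table."""
    if path is None:
        ref = resources.files("imsp.data") / "pcp_index.csv"
        raw = ref.read_bytes()
        if verify and hashlib.sha256(raw).hexdigest() != PCP_INDEX_SHA256:
            raise EncodingError("shipped pcp_index.csv checksum mismatch")
        import io
        df = pd.read_csv(io.BytesIO(raw), index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    df = df[list(STANDARD_AA)]
    return PCPIndexTable(values=df.to_numpy(float),
                         property_names=list(df.index))


# ---------------------------------------------------------------------------
# Individual encoders
# ---------------------------------------------------------------------------

def raw_aac(record: ProteinRecord) -> np.ndarray:
    """The 20 residue frequencies over the standard residues of the sequence."""
    counts = np.zeros(20)
    for c in record.seq:
        i = _AA_INDEX.get(c)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise EncodingError(
            f"record {record.id!r}: no standard residues to encode")
    return counts / total


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Affine map of a vector onto [-1, 1]: ((x-min)/(max-min) - 1/2) * 2.

    A constant vector maps to all zeros (the midpoint image, the continuous
    limit of the centring).
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise EncodingError("cannot normalise an empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return ((v - lo) / (hi - lo) - 0.5) * 2.0


def encode_aac(record: ProteinRecord) -> np.ndarray:
    return minmax_normalize(raw_aac(record))


def encode_mtf(record: ProteinRecord,
               motifs: Sequence[MotifPattern]) -> np.ndarray:
    """+1 where the motif occurs anywhere in the sequence, else -1."""
    if not motifs:
        raise EncodingError("motif list is empty")
    seq = record.seq
    return np.array([1.0 if pattern_regex(m.pattern).search(seq) else -1.0
                     for m in motifs])


def pcp_profile(record: ProteinRecord, table: PCPIndexTable) -> np.ndarray:
    """The 10 x L property profile over the standard residues of the sequence.

    Column j of the profile is the index-table column of the j-th standard
    residue (the matrix product of the table with the one-hot sequence
    matrix); ambiguity codes contribute no column.
    """
    idx = [_AA_INDEX[c] for c in record.seq if c in _AA_INDEX]
    if not idx:
        raise EncodingError(
            f"record {record.id!r}: no standard residues to encode")
    return table.values[:, idx]


def encode_pcp(record: ProteinRecord, table: PCPIndexTable,
               mode: Literal["mean_sd", "mean_only"] = "mean_sd",
               normalize: bool = True) -> np.ndarray:
    """Per-property summaries of the residue property profile.

    ``mean_sd`` (default): 10 per-property means followed by 10 per-property
    population standard deviations — 20 elements.  ``mean_only``: the 10
    means.  With ``normalize`` the vector is min-max mapped to [-1, 1]
    within the record.
    """
    profile = pcp_profile(record, table)
    means = profile.mean(axis=1)
    if mode == "mean_sd":
        vec = np.concatenate([means, profile.std(axis=1)])
    elif mode == "mean_only":
        vec = means
    else:
        raise EncodingError(f"unknown pcp mode {mode!r}")
    return minmax_normalize(vec) if normalize else vec


# ---------------------------------------------------------------------------
# Dataset-level feature matrix
# ---------------------------------------------------------------------------

def feature_names(n_motifs: int = 20,
                  pcp_mode: str = "mean_sd",
                  n_properties: int = 10) -> list[str]:
    names = [f"aac_{a}" for a in STANDARD_AA]
    names += [f"mtf_{i + 1}" for i in range(n_motifs)]
    names += [f"pcp_mean_{i + 1}" for i in range(n_properties)]
    if pcp_mode == "mean_sd":
        names += [f"pcp_sd_{i + 1}" for i in range(n_properties)]
    return names


@dataclass
class FeatureMatrix:
    """Named numeric feature matrix with a row-to-record mapping."""

    X: pd.DataFrame          # index = record ids, columns = feature names
    labels: pd.Series        # aligned to X.index; values in {1, -1} or NaN
    failures: list[str]      # per-record encoding failure messages

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def y(self) -> np.ndarray:
        """Labels as a +1/-1 array; raises if any row is unlabeled."""
        if self.labels.isna().any():
            raise EncodingError("feature matrix contains unlabeled rows")
        return self.labels.to_numpy(float)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(X=self.X[list(names)], labels=self.labels,
                             failures=self.failures)


def encode_dataset(ds: Dataset, motifs: Sequence[MotifPattern],
                   table: PCPIndexTable | None = None,
                   pcp_mode: Literal["mean_sd", "mean_only"] = "mean_sd",
                   pcp_scaling: Literal["record", "dataset"] = "record",
                   ) -> FeatureMatrix:
    """Encode every record; offending rows are dropped with a report.

    ``pcp_scaling='dataset'`` applies the [-1, 1] min-max per feature column
    across the dataset instead of within each record's vector.
    """
    if not motifs:
        raise EncodingError("motif list is empty; mine motifs first")
    if table is None:
        table = load_pcp_table()
    rows, ids, labels, failures = [], [], [], []
    for rec in ds:
        try:
            aac = encode_aac(rec)
            mtf = encode_mtf(rec, motifs)
            pcp = encode_pcp(rec, table, mode=pcp_mode,
                             normalize=(pcp_scaling == "record"))
            rows.append(np.concatenate([aac, mtf, pcp]))
            ids.append(rec.id)
            labels.append({"SP": 1.0, "nonSP": -1.0}.get(rec.label, np.nan))
        except EncodingError as exc:
            failures.append(str(exc))
    if not rows:
        raise EncodingError("all records failed to encode")
    names = feature_names(len(motifs), pcp_mode)
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"),
                     columns=names)
    if pcp_scaling == "dataset":
        pcp_cols = [c for c in names if c.startswith("pcp_")]
        X[pcp_cols] = np.apply_along_axis(minmax_normalize, 0,
                                          X[pcp_cols].to_numpy())
    return FeatureMatrix(X=X, labels=pd.Series(labels, index=X.index),
                         failures=failures)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    out = fm.X.copy()
    out.insert(0, "label", fm.labels)
    out.to_csv(path, sep="\t")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    labels = df.pop("label")
    return FeatureMatrix(X=df, labels=labels, failures=[])
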