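"""Protein sequence I/O, alphabet policy, redundancy reduction and dataset splitting.

A :class:`Dataset` is the pipeline's basic container: an ordered list of
:class:`ProteinRecord` objects, each an identifier, an uppercase residue
string, and optional species tag and secreted/non-secreted label.

Redundancy reduction follows the "cluster at 30% identity, keep the longest
member" policy using a greedy k-mer surrogate for pairwise identity (no
external aligner): estimated identity between two sequences is the number of
3-mers they share divided by the number of distinct 3-mers of the shorter
sequence.  Clustering is greedy longest-first, so every cluster
representative is its founder and therefore its longest member.

The train/test split draws ``floor(fraction * numP)`` positives plus an equal
number of negatives for training (balanced by construction); everything else
goes to the independent test set.  No positive is ever discarded.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity/rare codes tolerated at parse time.  They never contribute to
#: composition or property profiles and never match motifs.
AMBIGUOUS_AA = "XBZUOJ"

_ALLOWED = set(STANDARD_AA) | set(AMBIGUOUS_AA)

POSITIVE_LABEL = "SP"
NEGATIVE_LABEL = "nonSP"

SPECIES_TAGS = ("U", "H", "M", "B", "C", "O")


class ValidationError(ValueError):
    """Raised for records or datasets violating the input contracts."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, uppercase sequence, optional species tag and label."""

    id: str
    seq: str
    species: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted({c for c in self.seq if c not in _ALLOWED})
        if bad:
            raise ValidationError(
                f"record {self.id!r}: characters outside the tolerated "
                f"alphabet: {''.join(bad)}"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE_LABEL


@dataclass
class Dataset:
    """Ordered collection of protein records with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        dups = []
        for r in self.records:
            if r.id in seen:
                dups.append(r.id)
            seen[r.id] = 1
        if dups:
            raise ValidationError(f"duplicate record ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def num_pos(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE_LABEL)

    @property
    def num_neg(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE_LABEL)

    def positives(self) -> "Dataset":
        return Dataset([r for r in self.records if r.label == POSITIVE_LABEL])

    def negatives(self) -> "Dataset":
        return Dataset([r for r in self.records if r.label == NEGATIVE_LABEL])

    def subset_species(self, tag: str) -> "Dataset":
        return Dataset([r for r in self.records if r.species == tag])

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class DatasetSplit:
    """Balanced training set + independent test set, plus the seed used."""

    train: Dataset
    test: Dataset
    seed: int


# ---------------------------------------------------------------------------
# FASTA / label-table I/O
# ---------------------------------------------------------------------------

def read_label_table(path: str | Path) -> dict[str, tuple[str | None, str | None]]:
    """Read a sidecar TSV with columns (id, label, species).

    A header line starting with 'id' is skipped.  Missing columns yield None.
    """
    table: dict[str, tuple[str | None, str | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "id":
                continue
            rid = parts[0]
            label = parts[1] if len(parts) > 1 and parts[1] else None
            species = parts[2] if len(parts) > 2 and parts[2] else None
            table[rid] = (label, species)
    return table


def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    """Parse the '>id|label|species' header convention."""
    parts = header.split("|")
    rid = parts[0]
    label = parts[1] if len(parts) > 1 and parts[1] in (POSITIVE_LABEL, NEGATIVE_LABEL) else None
    species = parts[2] if len(parts) > 2 and parts[2] else None
    return rid, label, species


def read_fasta(
    path: str | Path,
    label_map: Mapping[str, tuple[str | None, str | None]] | None = None,
) -> tuple[Dataset, list[str]]:
    """Read a FASTA file into a :class:`Dataset`.

    Labels and species come from ``label_map`` (id -> (label, species)) when
    given, else from the ``>id|label|species`` header convention.  Sequences
    are uppercased; records with characters outside the tolerated alphabet
    are rejected and reported, not fatal.

    Returns ``(dataset, rejected_report)`` where the report lists one message
    per invalid record.
    """
    records: list[ProteinRecord] = []
    rejected: list[str] = []
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        rid, label, species = _parse_header(entry.id)
        if label_map is not None and rid in label_map:
            label, species = label_map[rid]
        try:
            records.append(
                ProteinRecord(id=rid, seq=str(entry.seq).upper(),
                              species=species, label=label)
            )
        except ValidationError as exc:
            rejected.append(str(exc))
    if n_entries == 0:
        logger.warning("no FASTA records found in %s", path)
    return Dataset(records), rejected


def write_fasta(ds: Dataset, path: str | Path) -> None:
    """Write records as FASTA using the '>id|label|species' convention."""
    with open(path, "w") as fh:
        for r in ds:
            label = r.label or ""
            species = r.species or ""
            header = r.id if not (label or species) else f"{r.id}|{label}|{species}"
            fh.write(f">{header}\n")
            for i in range(0, len(r.seq), 70):
                fh.write(r.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def estimated_identity(a: str, b: str, k: int = 3) -> float:
    """k-mer identity surrogate: |shared k-mers| / |k-mers of shorter seq|."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ks = _kmer_set(short, k)
    if not ks:
        return 0.0
    return len(ks & _kmer_set(long_, k)) / len(ks)


def reduce_redundancy(ds: Dataset, identity_threshold: float = 0.30) -> Dataset:
    """Greedy longest-first clustering; keep each cluster's longest member.

    Records are visited longest first (ties broken by input order); each
    joins the first cluster whose representative it matches at or above the
    threshold, else founds a new cluster.  Because visiting order is
    longest-first, each founder is its cluster's longest member and is the
    representative kept.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    order = sorted(range(len(ds.records)),
                   key=lambda i: (-len(ds.records[i].seq), i))
    reps: list[ProteinRecord] = []
    for i in order:
        rec = ds.records[i]
        for rep in reps:
            if estimated_identity(rec.seq, rep.seq) >= identity_threshold:
                break
        else:
            reps.append(rec)
    # restore input order among the kept representatives
    kept = {r.id for r in reps}
    return Dataset([r for r in ds.records if r.id in kept])


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_counts(num_pos: int, num_neg: int, train_fraction: float = 4 / 5
                 ) -> tuple[int, int, int, int]:
    """Return (trainP, trainN, testP, testN) for the balanced-split policy.

    trainP = floor(train_fraction * numP); trainN = trainP; the remainder of
    both classes goes to testing.
    """
    train_p = int(train_fraction * num_pos)
    if num_neg < train_p:
        raise ValidationError(
            f"insufficient negatives: need {train_p}, have {num_neg}")
    return train_p, train_p, num_pos - train_p, num_neg - train_p


def split_dataset(ds: Dataset, train_fraction: float = 4 / 5,
                  seed: int = 0) -> DatasetSplit:
    """Balanced train / independent-test split, deterministic given seed.

    Training takes ``floor(train_fraction * numP)`` randomly chosen positives
    and an equal number of randomly chosen negatives; all remaining records
    of both classes form the test set.
    """
    pos = [r for r in ds.records if r.label == POSITIVE_LABEL]
    neg = [r for r in ds.records if r.label == NEGATIVE_LABEL]
    if len(pos) < 2:
        raise ValidationError(f"need >= 2 positives, have {len(pos)}")
    train_p, train_n, _, _ = split_counts(len(pos), len(neg), train_fraction)
    rng = random.Random(seed)
    pos_idx = list(range(len(pos)))
    neg_idx = list(range(len(neg)))
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    train_pos = {pos[i].id for i in pos_idx[:train_p]}
    train_neg = {neg[i].id for i in neg_idx[:train_n]}
    chosen = train_pos | train_neg
    train = Dataset([r for r in ds.records if r.id in chosen])
    test = Dataset([r for r in ds.records
                    if r.id not in chosen and r.label is not None])
    return DatasetSplit(train=train, test=test, seed=seed)


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    """TSV manifest: (id, partition, label)."""
    with open(path, "w") as fh:
        fh.write("id\tpartition\tlabel\n")
        for part, ds in (("train", split.train), ("test", split.test)):
            for r in ds:
                fh.write(f"{r.id}\t{part}\t{r.label or ''}\n")
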