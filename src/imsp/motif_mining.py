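"""Discriminative wildcard-motif mining scored by information gain and RDI.

A motif is a short pattern over the 20 standard residues with at most one
internal wildcard ``-`` (matching any single standard residue), 3-5 literal
positions and total length at most 6 — e.g. ``KGD``, ``LLLL``, ``LL-LLL``.

Scoring uses information theory.  For a set of N proteins the set entropy is
``I(S) = log2 N``.  Partitioning by presence of motif M, with p the fraction
of proteins containing M, gives the conditional entropy

    I(S|M) = p*log2(p*N) + (1-p)*log2((1-p)*N)

so the information gain IG(M) = I(S) - I(S|M) reduces to the binary entropy
of p: it is 0 when M is ubiquitous or absent and maximal (1 bit) at p = 0.5.
Because raw IG is blind to which class the motif favours and is skewed by
class imbalance, motifs are ranked by the ratio-of-difference-of-IG (RDI):

    RDI(M) = IGP(M)/IP(S) - IGN(M)/IN(S)

where IGP/IGN are the gains computed on positives and negatives alone and
IP(S)/IN(S) are the corresponding set entropies.  The normalisation by set
entropy makes RDI invariant to the logarithm base and offsets unequal class
sizes.  Single-member class sets are rejected: their entropy is 0 and the
ratio is undefined.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .sequences import Dataset, STANDARD_AA

logger = logging.getLogger(__name__)

WILDCARD = "-"

#: Allowed motif shapes: (total_length, literal_count).  At most one internal
#: wildcard, 3-5 literals, total length <= 6.
MIN_LITERALS = 3
MAX_LITERALS = 5
MAX_LENGTH = 6

_STANDARD_SET = frozenset(STANDARD_AA)


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A scored wildcard motif."""

    pattern: str
    n_literal: int
    count_pos: int = 0
    count_neg: int = 0
    ig_pos: float = 0.0
    ig_neg: float = 0.0
    rdi: float = 0.0

    def __post_init__(self) -> None:
        validate_pattern(self.pattern)


def validate_pattern(pattern: str) -> None:
    if not pattern:
        raise MotifError("empty pattern")
    if pattern[0] == WILDCARD or pattern[-1] == WILDCARD:
        raise MotifError(f"pattern {pattern!r} starts or ends with a wildcard")
    n_wild = pattern.count(WILDCARD)
    n_lit = len(pattern) - n_wild
    if n_wild > 1:
        raise MotifError(f"pattern {pattern!r} has more than one wildcard")
    if not MIN_LITERALS <= n_lit <= MAX_LITERALS:
        raise MotifError(
            f"pattern {pattern!r} has {n_lit} literals, need "
            f"{MIN_LITERALS}-{MAX_LITERALS}")
    if len(pattern) > MAX_LENGTH:
        raise MotifError(f"pattern {pattern!r} longer than {MAX_LENGTH}")
    bad = set(pattern) - _STANDARD_SET - {WILDCARD}
    if bad:
        raise MotifError(f"pattern {pattern!r} has invalid characters {bad}")


def pattern_regex(pattern: str) -> re.Pattern:
    """Compile a motif into a regex; the wildcard matches one standard residue.

    Ambiguity codes (X, B, Z, U, O, J) match neither literals nor wildcards.
    """
    return re.compile("".join(
        f"[{STANDARD_AA}]" if c == WILDCARD else re.escape(c)
        for c in pattern))


def matches(pattern: str, seq: str) -> bool:
    """Presence/absence: does the motif occur anywhere in the sequence?"""
    return pattern_regex(pattern).search(seq.upper()) is not None


# ---------------------------------------------------------------------------
# Entropy / information gain / RDI
# ---------------------------------------------------------------------------

def set_entropy(n: int, base: float = 2.0) -> float:
    """Entropy of a set of n distinguishable proteins: log(n)."""
    if n < 1:
        raise MotifError(f"set size must be >= 1, got {n}")
    return math.log(n, base)


def conditional_entropy(p_m: float, n: int, base: float = 2.0) -> float:
    """Entropy after partitioning by motif presence at fraction p_m.

    ``p*log(p*n) + (1-p)*log((1-p)*n)`` with the convention 0*log(0) = 0.
    """
    if not 0.0 <= p_m <= 1.0:
        raise MotifError(f"p_m must be in [0, 1], got {p_m}")
    if n < 1:
        raise MotifError(f"set size must be >= 1, got {n}")
    out = 0.0
    for p in (p_m, 1.0 - p_m):
        if p > 0.0:
            out += p * math.log(p * n, base)
    return out


def information_gain(p_m: float, n: int, base: float = 2.0) -> float:
    """IG from partitioning by motif presence; equals the binary entropy of p_m."""
    ig = set_entropy(n, base) - conditional_entropy(p_m, n, base)
    return max(ig, 0.0)  # clamp -0.0 / rounding at the boundary


def compute_rdi(pattern: str, positives: Dataset, negatives: Dataset,
                base: float = 2.0) -> MotifPattern:
    """Score one motif on a positive and a negative protein set.

    Presence is counted per protein (anywhere in the sequence).  Both sets
    need at least two members: a singleton set has zero entropy and the
    entropy-normalised gain is undefined.
    """
    validate_pattern(pattern)
    n_pos, n_neg = len(positives), len(negatives)
    if n_pos < 2 or n_neg < 2:
        raise MotifError(
            f"need >= 2 proteins per class for RDI (got {n_pos} positives, "
            f"{n_neg} negatives); set entropy is 0 for singletons")
    rx = pattern_regex(pattern)
    count_pos = sum(1 for s in positives.sequences() if rx.search(s.upper()))
    count_neg = sum(1 for s in negatives.sequences() if rx.search(s.upper()))
    ig_pos = information_gain(count_pos / n_pos, n_pos, base)
    ig_neg = information_gain(count_neg / n_neg, n_neg, base)
    rdi = ig_pos / set_entropy(n_pos, base) - ig_neg / set_entropy(n_neg, base)
    n_lit = len(pattern) - pattern.count(WILDCARD)
    return MotifPattern(pattern=pattern, n_literal=n_lit,
                        count_pos=count_pos, count_neg=count_neg,
                        ig_pos=ig_pos, ig_neg=ig_neg, rdi=rdi)


# ---------------------------------------------------------------------------
# Candidate enumeration and mining
# ---------------------------------------------------------------------------

def _window_patterns(seq: str) -> set[str]:
    """All valid patterns instantiated by windows of one sequence.

    Every fully-standard window of length 3-5 yields its literal pattern;
    every fully-standard window of length 4-6 additionally yields the
    variants with one internal position replaced by the wildcard.  A window
    containing an ambiguity code yields nothing: such positions can match
    neither a literal nor the wildcard.
    """
    seq = seq.upper()
    out: set[str] = set()
    n = len(seq)
    for length in range(MIN_LITERALS, MAX_LENGTH + 1):
        for i in range(n - length + 1):
            w = seq[i:i + length]
            if not _STANDARD_SET.issuperset(w):
                continue
            if MIN_LITERALS <= length <= MAX_LITERALS:
                out.add(w)
            if length >= MIN_LITERALS + 1:  # room for one internal wildcard
                for j in range(1, length - 1):
                    if length - 1 <= MAX_LITERALS:
                        out.add(w[:j] + WILDCARD + w[j + 1:])
    return out


def enumerate_candidates(positives: Dataset, min_support: float = 0.05
                         ) -> list[str]:
    """Candidate motifs observed in at least ``min_support`` of positives.

    Patterns are generated only from windows actually present in the positive
    sequences (never by free alphabet enumeration), then filtered by
    per-protein support.  Returned sorted for determinism.
    """
    if len(positives) == 0:
        raise MotifError("positive set is empty")
    if not 0.0 < min_support <= 1.0:
        raise MotifError(f"min_support must be in (0, 1], got {min_support}")
    counts: dict[str, int] = {}
    for seq in positives.sequences():
        for pat in _window_patterns(seq):
            counts[pat] = counts.get(pat, 0) + 1
    needed = min_support * len(positives)
    return sorted(p for p, c in counts.items() if c >= needed)


def _presence_counts(patterns: Iterable[str], ds: Dataset) -> dict[str, int]:
    """Per-protein presence counts for many patterns at once.

    Exact for this pattern class: a pattern occurs in a sequence iff it is
    instantiated by one of the sequence's windows.
    """
    wanted = set(patterns)
    counts = {p: 0 for p in wanted}
    for seq in ds.sequences():
        for pat in _window_patterns(seq) & wanted:
            counts[pat] += 1
    return counts


def mine_top_motifs(positives: Dataset, negatives: Dataset, k: int = 20,
                    min_support: float = 0.05, base: float = 2.0
                    ) -> list[MotifPattern]:
    """Mine and rank motifs; return the top k by RDI.

    Candidates come from the positive set at the given support; each is
    scored by RDI against the negative set.  Ordering is RDI descending with
    deterministic tie-breaks: higher positive count first, then lexicographic
    pattern.  If fewer than k candidates exist, all are returned.
    """
    if k < 1:
        raise MotifError(f"k must be >= 1, got {k}")
    n_pos, n_neg = len(positives), len(negatives)
    if n_pos < 2 or n_neg < 2:
        raise MotifError("need >= 2 proteins per class")
    candidates = enumerate_candidates(positives, min_support)
    pos_counts = _presence_counts(candidates, positives)
    neg_counts = _presence_counts(candidates, negatives)
    ip = set_entropy(n_pos, base)
    in_ = set_entropy(n_neg, base)
    scored: list[MotifPattern] = []
    for pat in candidates:
        cp, cn = pos_counts[pat], neg_counts[pat]
        ig_p = information_gain(cp / n_pos, n_pos, base)
        ig_n = information_gain(cn / n_neg, n_neg, base)
        scored.append(MotifPattern(
            pattern=pat, n_literal=len(pat) - pat.count(WILDCARD),
            count_pos=cp, count_neg=cn, ig_pos=ig_p, ig_neg=ig_n,
            rdi=ig_p / ip - ig_n / in_))
    scored.sort(key=lambda m: (-m.rdi, -m.count_pos, m.pattern))
    if len(scored) < k:
        logger.warning("only %d candidate motifs for k=%d", len(scored), k)
    return scored[:k]


# ---------------------------------------------------------------------------
# Motif table I/O
# ---------------------------------------------------------------------------

_TSV_HEADER = "pattern\tn_literal\tcount_pos\tcount_neg\tig_pos\tig_neg\trdi"


def write_motif_table(motifs: Sequence[MotifPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for m in motifs:
            fh.write(f"{m.pattern}\t{m.n_literal}\t{m.count_pos}\t"
                     f"{m.count_neg}\t{m.ig_pos:.10g}\t{m.ig_neg:.10g}\t"
                     f"{m.rdi:.10g}\n")


def read_motif_table(path: str | Path) -> list[MotifPattern]:
    motifs: list[MotifPattern] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _TSV_HEADER:
            raise MotifError(f"unexpected motif table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            pat, nlit, cp, cn, igp, ign, rdi = line.rstrip("\n").split("\t")
            motifs.append(MotifPattern(
                pattern=pat, n_literal=int(nlit), count_pos=int(cp),
                count_neg=int(cn), ig_pos=float(igp), ig_neg=float(ign),
                rdi=float(rdi)))
    return motifs
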