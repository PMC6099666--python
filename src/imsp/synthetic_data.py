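"""Labeled synthetic protein datasets with controllable class signal.

The generator emulates the three ways secreted and non-secreted proteins
differ in the features this package computes, without attempting real
secretome biology (no signal peptides, no disorder):

* class-differential residue composition — per-residue log2 fold changes
  applied to the positive class's sampling distribution,
* planted motifs — short patterns written into a Bernoulli-selected subset
  of each class at a uniform random position (overwriting residues, so
  sequence length and approximate composition are preserved),
* the resulting physicochemical property shifts that follow from the
  composition change.

Sequences are drawn i.i.d. per residue; lengths are uniform over a range.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .motif_mining import WILDCARD, validate_pattern
from .sequences import (Dataset, ProteinRecord, STANDARD_AA,
                        NEGATIVE_LABEL, POSITIVE_LABEL)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Parameters of one labeled, single-species synthetic dataset."""

    n_pos: int = 150
    n_neg: int = 150
    species: str = "U"
    length_range: tuple[int, int] = (80, 160)
    base_composition: dict[str, float] | None = None   # default: uniform
    composition_shift: dict[str, float] = field(default_factory=dict)  # log2 FC, positives
    planted_motifs: list[tuple[str, float, float]] = field(default_factory=list)
    # ^ (pattern, prevalence in positives, prevalence in negatives)
    seed: int = 0
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("need at least one sequence per class")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"bad length range {self.length_range}")
        for pat, pp, pn in self.planted_motifs:
            validate_pattern(pat)
            if not (0 <= pp <= 1 and 0 <= pn <= 1):
                raise ConfigError(f"prevalences for {pat!r} must be in [0, 1]")
            if len(pat) > lo:
                raise ConfigError(
                    f"motif {pat!r} longer than minimum sequence length {lo}")

    def compositions(self) -> tuple[np.ndarray, np.ndarray]:
        """(negative-class, positive-class) residue sampling distributions."""
        if self.base_composition is None:
            base = np.full(20, 1 / 20)
        else:
            base = np.array([self.base_composition.get(a, 0.0)
                             for a in STANDARD_AA])
            if base.min() < 0 or not np.isclose(base.sum(), 1.0):
                raise ConfigError("base_composition is not a probability vector")
        shifted = base * np.array(
            [2.0 ** self.composition_shift.get(a, 0.0) for a in STANDARD_AA])
        return base, shifted / shifted.sum()


def _draw_sequence(rng: np.random.Generator, comp: np.ndarray,
                   lo: int, hi: int) -> list[str]:
    length = int(rng.integers(lo, hi + 1))
    return [STANDARD_AA[i] for i in rng.choice(20, size=length, p=comp)]


def _plant(rng: np.random.Generator, seq: list[str], pattern: str) -> None:
    pos = int(rng.integers(0, len(seq) - len(pattern) + 1))
    for j, c in enumerate(pattern):
        seq[pos + j] = (STANDARD_AA[int(rng.integers(0, 20))]
                        if c == WILDCARD else c)


def generate(config: SyntheticConfig) -> Dataset:
    """Draw one labeled dataset; byte-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    neg_comp, pos_comp = config.compositions()
    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    for label, n, comp in ((POSITIVE_LABEL, config.n_pos, pos_comp),
                           (NEGATIVE_LABEL, config.n_neg, neg_comp)):
        tag = "p" if label == POSITIVE_LABEL else "n"
        for i in range(n):
            seq = _draw_sequence(rng, comp, lo, hi)
            for pattern, prev_pos, prev_neg in config.planted_motifs:
                prev = prev_pos if label == POSITIVE_LABEL else prev_neg
                if rng.random() < prev:
                    _plant(rng, seq, pattern)
            records.append(ProteinRecord(
                id=f"{config.id_prefix}_{config.species}_{tag}{i:04d}",
                seq="".join(seq), species=config.species, label=label))
    return Dataset(records)


def generate_multispecies(configs: Sequence[SyntheticConfig]) -> Dataset:
    """Concatenate per-species datasets (ids must not collide)."""
    records: list[ProteinRecord] = []
    for cfg in configs:
        records.extend(generate(cfg).records)
    return Dataset(records)


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

def make_benchmark_suite(seed: int = 0) -> dict[str, Dataset]:
    """The named fixtures used across the test and evaluation suite.

    * ``separable`` — strong composition shift plus three planted motifs;
      a classifier should approach perfect pooled-CV MCC.
    * ``null`` — no class signal at all; accuracy should hover at chance.
    * ``motif-only`` — a single planted motif (prevalence 0.60 vs 0.05),
      no composition difference; n = 200 per class.
    * ``composition-only`` — composition shift without motifs.
    * ``two-species-divergent`` — two species whose positive-class signals
      point in opposite directions (leucine-rich vs leucine-poor, motif
      roles swapped), so a pooled model must compromise while per-species
      models need not.
    """
    suite: dict[str, Dataset] = {}
    suite["separable"] = generate(SyntheticConfig(
        n_pos=150, n_neg=150, species="U", length_range=(80, 160),
        composition_shift={"L": 1.0, "A": 0.8, "G": 0.8, "K": -1.0, "E": -0.8},
        planted_motifs=[("LLLL", 0.9, 0.05), ("KGD", 0.7, 0.05),
                        ("CCP", 0.6, 0.05)],
        seed=seed, id_prefix="sep"))
    suite["null"] = generate(SyntheticConfig(
        n_pos=150, n_neg=150, species="U", length_range=(80, 160),
        seed=seed + 1, id_prefix="nul"))
    suite["motif-only"] = generate(SyntheticConfig(
        n_pos=200, n_neg=200, species="U", length_range=(60, 100),
        planted_motifs=[("KGD", 0.60, 0.05)],
        seed=seed + 2, id_prefix="mtf"))
    suite["composition-only"] = generate(SyntheticConfig(
        n_pos=150, n_neg=150, species="U", length_range=(80, 160),
        composition_shift={"L": 1.0, "G": 0.8, "K": -1.0},
        seed=seed + 3, id_prefix="cmp"))
    suite["two-species-divergent"] = generate_multispecies([
        SyntheticConfig(
            n_pos=120, n_neg=120, species="H", length_range=(80, 140),
            composition_shift={"L": 1.2, "A": 0.6, "K": -0.8},
            planted_motifs=[("LLLL", 0.8, 0.05), ("KGD", 0.05, 0.6)],
            seed=seed + 4, id_prefix="dvh"),
        SyntheticConfig(
            n_pos=120, n_neg=120, species="M", length_range=(80, 140),
            composition_shift={"L": -1.2, "G": 0.8, "K": 0.8},
            planted_motifs=[("KGD", 0.8, 0.05), ("LLLL", 0.05, 0.6)],
            seed=seed + 5, id_prefix="dvm"),
    ])
    return suite


def write_manifest(config: SyntheticConfig, path: str | Path) -> None:
    """JSON manifest echoing the generating config and seed."""
    Path(path).write_text(json.dumps(asdict(config), indent=2, default=list))
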