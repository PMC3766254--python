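"""Mamdani fuzzy inference from ordinal levels to crisp edge weights.

Each directed influence carries three linguistic levels on the scale
VL < L < M < H < VH. The levels index triangular fuzzy sets partitioning the
unit interval:

    VL = (0, 0, 0.25)      L = (0, 0.25, 0.5)     M = (0.25, 0.5, 0.75)
    H  = (0.5, 0.75, 1)    VH = (0.75, 1, 1)

VL and VH are boundary shoulders; the interior sets are symmetric hats of
half-width 0.25. Every rule antecedent is the binary presence of the source
concept ("ON"), so all three rules fire at full strength and min-implication
is degenerate: the consequent sets pass through unchanged. Aggregation is the
pointwise maximum of the three sets sampled on a uniform grid, and the crisp
magnitude is the centroid (centre of mass) of the aggregate computed by the
trapezoid rule. The influence sign is applied after defuzzification, so
magnitudes always lie in (0, 1) and signed weights in (-1, 1).

With this partition the fully interior worked cases are exact — {L,L,L}
defuzzifies to 0.25 and {M,L,H} to 0.5 — while cases touching a boundary
shoulder (e.g. {M,H,VH} -> 2/3) depend on the precise shoulder realisation;
see docs/methods.md for the calibration discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from lingfcm.fcm_engine import ConceptMap
from lingfcm.knowledge_base import (
    EdgeEvidence,
    KnowledgeBase,
    LinguisticLevel,
    ValidationError,
)


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with support [left, right], peak 1."""

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.left <= self.peak <= self.right <= 1.0):
            raise ValidationError(
                f"require 0 <= left <= peak <= right <= 1, got "
                f"({self.left}, {self.peak}, {self.right})"
            )

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.peak > self.left:
            rising = (x >= self.left) & (x <= self.peak)
            out[rising] = (x[rising] - self.left) / (self.peak - self.left)
        else:                      # left shoulder: full membership at the peak
            out[x <= self.peak] = 1.0
        if self.right > self.peak:
            falling = (x > self.peak) & (x <= self.right)
            out[falling] = (self.right - x[falling]) / (self.right - self.peak)
        else:                      # right shoulder
            out[x >= self.peak] = 1.0
        return out if out.ndim else float(out)


def membership_degree(x: float, mf: TriangularMF) -> float:
    """Evaluate a triangular membership function at a point."""
    return float(mf(x))


_DEFAULT_MFS: dict[LinguisticLevel, TriangularMF] = {
    LinguisticLevel.VL: TriangularMF(0.0, 0.0, 0.25),
    LinguisticLevel.L: TriangularMF(0.0, 0.25, 0.5),
    LinguisticLevel.M: TriangularMF(0.25, 0.5, 0.75),
    LinguisticLevel.H: TriangularMF(0.5, 0.75, 1.0),
    LinguisticLevel.VH: TriangularMF(0.75, 1.0, 1.0),
}


@dataclass(frozen=True)
class FuzzyPartition:
    """Five triangular fuzzy sets over [0, 1] plus the sampling grid."""

    mfs: dict[LinguisticLevel, TriangularMF] = field(
        default_factory=lambda: dict(_DEFAULT_MFS)
    )
    grid_points: int = 1001

    def __post_init__(self) -> None:
        if set(self.mfs) != set(LinguisticLevel):
            raise ValidationError("partition must define all five levels")
        if self.grid_points < 101:
            raise ValidationError("grid_points must be >= 101")
        grid = self.grid()
        coverage = np.max(
            np.vstack([mf(grid) for mf in self.mfs.values()]), axis=0
        )
        if np.any(coverage <= 0.0):
            raise ValidationError("partition leaves part of [0,1] uncovered")

    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid_points)


@dataclass(frozen=True)
class AggregatedSet:
    """Aggregated consequent membership sampled on the uniform grid."""

    grid: np.ndarray
    membership: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != self.membership.shape:
            raise ValidationError("grid/membership length mismatch")
        if np.any((self.membership < 0) | (self.membership > 1)):
            raise ValidationError("membership values must lie in [0, 1]")


def aggregate_rules(
    levels: Sequence[LinguisticLevel], partition: FuzzyPartition | None = None
) -> AggregatedSet:
    """Max-aggregate the consequent sets of full-strength rules.

    Every rule antecedent is the binary "ON" of the source concept, so each
    consequent set enters at full height; the aggregate is their pointwise
    maximum on the partition grid.
    """
    if partition is None:
        partition = FuzzyPartition()
    if len(levels) == 0:
        raise ValidationError("need at least one rule consequent")
    grid = partition.grid()
    stacked = np.vstack([partition.mfs[lv](grid) for lv in levels])
    return AggregatedSet(grid=grid, membership=np.max(stacked, axis=0))


def defuzzify_centroid(agg: AggregatedSet) -> float:
    """Centre of mass of the aggregate, by the trapezoid rule."""
    area = float(np.trapezoid(agg.membership, agg.grid))
    if area <= 0.0:
        raise ValidationError("cannot defuzzify an all-zero aggregate")
    moment = float(np.trapezoid(agg.grid * agg.membership, agg.grid))
    return moment / area


def fuzzy_magnitude(
    levels: Sequence[LinguisticLevel], partition: FuzzyPartition | None = None
) -> float:
    """Unsigned defuzzified weight for a triple of linguistic levels."""
    return defuzzify_centroid(aggregate_rules(levels, partition))


def edge_weight(
    ev: EdgeEvidence, partition: FuzzyPartition | None = None
) -> float:
    """Signed crisp weight for one evidence edge (sign applied last)."""
    return ev.sign * fuzzy_magnitude(ev.levels, partition)


def weight_matrix(
    kb: KnowledgeBase, partition: FuzzyPartition | None = None
) -> ConceptMap:
    """Assemble the full signed weight matrix from a knowledge base.

    Entry ``W[j, i]`` holds the defuzzified signed weight of the edge from
    concept ``j`` to concept ``i``; absent edges are 0 and the diagonal is
    left at 0 (self-influence is a simulation setting, not a weight).
    """
    if partition is None:
        partition = FuzzyPartition()
    n = kb.n_concepts
    index = {name: i for i, name in enumerate(kb.concepts)}
    W = np.zeros((n, n))
    for ev in kb.edges:
        W[index[ev.source], index[ev.target]] = edge_weight(ev, partition)
    return ConceptMap(concepts=kb.concepts, W=W)


def mirror_levels(
    levels: Iterable[LinguisticLevel],
) -> tuple[LinguisticLevel, ...]:
    """Reflect each level about the scale midpoint (VL<->VH, L<->H)."""
    return tuple(lv.mirror() for lv in levels)
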