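"""Seeded generators for synthetic maps, evidence, and scenarios.

The generators target the structural properties the analysis assumes — a
signed weighted digraph without self-edges, optionally with a designated
outcome-only sink concept (mimicking the role of homelessness), edge
magnitudes inside (0, 1], and three-level linguistic evidence per edge — so
every pipeline stage can be exercised without any external data. They make
no attempt at statistical realism of social indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from lingfcm.fcm_engine import ConceptMap, SimulationSettings
from lingfcm.knowledge_base import EdgeEvidence, LinguisticLevel, ValidationError
from lingfcm.scenarios import ScenarioSpec

#: Name given to the designated outcome-only concept of synthetic maps.
SINK_NAME = "Outcome"


@dataclass
class SyntheticMapSpec:
    """Parameters of a random concept map.

    density is the fraction of admissible ordered pairs (no self-edges; no
    edges out of the sink when one is designated) that receive an edge.
    """

    n_concepts: int
    density: float = 0.2
    weight_range: tuple[float, float] = (0.25, 1.0)
    negative_fraction: float = 0.3
    sink_concept: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValidationError("need at least 2 concepts")
        if not (0.0 < self.density <= 1.0):
            raise ValidationError("density must be in (0, 1]")
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("weight_range must be a sub-interval of (0, 1]")
        if not (0.0 <= self.negative_fraction <= 1.0):
            raise ValidationError("negative_fraction must be in [0, 1]")


def random_map(spec: SyntheticMapSpec) -> ConceptMap:
    """Draw a reproducible random signed weighted map.

    The sink concept, when designated, is the first concept (named
    ``"Outcome"``) and has no outgoing edges. The number of edges is
    ``round(density * n_admissible_pairs)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_concepts
    if spec.sink_concept:
        concepts = (SINK_NAME,) + tuple(f"C{i}" for i in range(1, n))
    else:
        concepts = tuple(f"C{i}" for i in range(1, n + 1))
    pairs = [
        (j, i)
        for j in range(n)
        for i in range(n)
        if j != i and not (spec.sink_concept and j == 0)
    ]
    n_edges = round(spec.density * len(pairs))
    if n_edges < 1:
        raise ValidationError(
            f"density {spec.density} yields no edges on {n} concepts"
        )
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    lo, hi = spec.weight_range
    W = np.zeros((n, n))
    for k in chosen:
        j, i = pairs[k]
        magnitude = rng.uniform(lo, hi)
        sign = -1.0 if rng.random() < spec.negative_fraction else 1.0
        W[j, i] = sign * magnitude
    return ConceptMap(concepts=concepts, W=W)


def random_evidence(n_edges: int, seed: int = 0) -> list[EdgeEvidence]:
    """Draw random evidence edges: uniform level triples, Bernoulli signs."""
    if n_edges < 0:
        raise ValidationError("n_edges must be >= 0")
    rng = np.random.default_rng(seed)
    if n_edges == 0:
        return []
    n_concepts = max(2, math.ceil((1 + math.sqrt(1 + 4 * n_edges)) / 2))
    names = [f"C{i}" for i in range(1, n_concepts + 1)]
    pairs = [(a, b) for a in names for b in names if a != b]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    levels = list(LinguisticLevel)
    out = []
    for k in chosen:
        src, tgt = pairs[k]
        triple = tuple(levels[i] for i in rng.integers(0, 5, size=3))
        sign = -1 if rng.random() < 0.5 else 1
        out.append(EdgeEvidence(src, tgt, sign, triple))  # type: ignore[arg-type]
    return out


def random_scenario(
    cmap: ConceptMap, n_active: int, seed: int = 0, outcome: str | None = None
) -> ScenarioSpec:
    """Activate a random non-outcome subset at uniform levels in [0, 1]."""
    rng = np.random.default_rng(seed)
    if outcome is None:
        outcome = SINK_NAME if SINK_NAME in cmap.concepts else cmap.concepts[0]
    candidates = [c for c in cmap.concepts if c != outcome]
    if n_active >= cmap.n:
        raise ValidationError("n_active must be smaller than the map size")
    picked = rng.choice(len(candidates), size=n_active, replace=False)
    activations = {
        candidates[i]: float(rng.uniform(0.0, 1.0)) for i in picked
    }
    return ScenarioSpec(
        activations=activations,
        settings=SimulationSettings(threshold="tanh", self_memory=1),
        label=f"synthetic scenario (seed={seed})",
        outcome=outcome,
    )
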