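"""Network analysis of a weighted concept map.

Degree centrality of a concept is the sum of the absolute weights of its
incoming and outgoing edges (self-loops excluded by default). Closeness
centrality uses inverse-weight distances d(x, y) = 1 / |w(x, y)| per edge:
the shortest directed path lengths are computed on true infinities first and
unreachable pairs are then replaced by a Big-M constant (default 100, far
above the longest possible finite path in the packaged map) inside the
closeness sum, so the penalty never contaminates multi-hop paths. The raw
closeness 1 / sum(d) is tiny whenever unreachable pairs exist, so a scaled
copy (default x 10^4) is reported alongside.

The one-at-a-time sensitivity sweep varies a single concept's initial value
over a grid while every other concept (except the outcome) starts at a small
common baseline, runs a fixed number of tanh iterations, and records the
outcome level — the protocol used to compare the leverage of individual
concepts, summarised per concept by box-plot quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from lingfcm.fcm_engine import ConceptMap, SimulationSettings, step
from lingfcm.knowledge_base import ValidationError, normalize_concept
from lingfcm.scenarios import DEFAULT_OUTCOME


@dataclass
class CentralitySettings:
    """Conventions for the centrality computations."""

    big_m: float = 100.0
    include_self_loops_in_degree: bool = False
    report_scale: float = 1e4

    def __post_init__(self) -> None:
        if self.big_m <= 0:
            raise ValidationError("big_m must be positive")


@dataclass
class CentralityReport:
    """Per-concept degree and closeness values with conventions recorded."""

    frame: pd.DataFrame          # concept, degree, closeness_raw, closeness_scaled
    settings: CentralitySettings

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def degree_centrality(
    cmap: ConceptMap, settings: CentralitySettings | None = None
) -> pd.Series:
    """Sum of absolute in- and out-edge weights per concept."""
    if settings is None:
        settings = CentralitySettings()
    W = np.abs(cmap.W)
    diag = np.diag(W).copy()
    totals = W.sum(axis=1) + W.sum(axis=0)
    if settings.include_self_loops_in_degree:
        pass                        # a self-loop counts once out + once in
    else:
        totals -= 2 * diag
    return pd.Series(totals, index=list(cmap.concepts), name="degree")


def _distance_graph(cmap: ConceptMap) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(cmap.n))
    for j in range(cmap.n):
        for i in range(cmap.n):
            if i != j and cmap.W[j, i] != 0.0:
                g.add_edge(j, i, dist=1.0 / abs(cmap.W[j, i]))
    return g


def shortest_paths(
    cmap: ConceptMap, settings: CentralitySettings | None = None
) -> pd.DataFrame:
    """All-pairs shortest directed path lengths over d = 1/|w|.

    Paths are computed on true infinities; unreachable pairs then hold the
    Big-M constant. The diagonal is 0.
    """
    if settings is None:
        settings = CentralitySettings()
    g = _distance_graph(cmap)
    D = np.full((cmap.n, cmap.n), np.inf)
    np.fill_diagonal(D, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="dist"):
        for tgt, dist in lengths.items():
            D[src, tgt] = dist
    D[np.isinf(D)] = settings.big_m
    return pd.DataFrame(D, index=list(cmap.concepts), columns=list(cmap.concepts))


def closeness_centrality(
    cmap: ConceptMap, settings: CentralitySettings | None = None
) -> pd.DataFrame:
    """Inverse of summed shortest-path distances to every other concept.

    Returns a frame with ``closeness_raw`` (1 / sum of distances, Big-M
    substituted for unreachable pairs) and ``closeness_scaled``
    (raw x report_scale). A single-concept map has no other concepts to
    reach; its closeness is reported as Big-M and flagged degenerate.
    """
    if settings is None:
        settings = CentralitySettings()
    D = shortest_paths(cmap, settings).to_numpy()
    n = cmap.n
    frame = pd.DataFrame(index=list(cmap.concepts))
    if n == 1:
        frame["closeness_raw"] = [settings.big_m]
        frame["closeness_scaled"] = [settings.big_m * settings.report_scale]
        frame["degenerate"] = [True]
        return frame
    sums = D.sum(axis=1)            # diagonal contributes 0
    raw = 1.0 / sums
    frame["closeness_raw"] = raw
    frame["closeness_scaled"] = raw * settings.report_scale
    frame["degenerate"] = False
    return frame


def centrality_report(
    cmap: ConceptMap, settings: CentralitySettings | None = None
) -> CentralityReport:
    """Degree plus closeness in one table."""
    if settings is None:
        settings = CentralitySettings()
    degree = degree_centrality(cmap, settings)
    close = closeness_centrality(cmap, settings)
    frame = pd.DataFrame(
        {
            "concept": list(cmap.concepts),
            "degree": degree.to_numpy(),
            "closeness_raw": close["closeness_raw"].to_numpy(),
            "closeness_scaled": close["closeness_scaled"].to_numpy(),
        }
    )
    return CentralityReport(frame=frame, settings=settings)


@dataclass
class SweepResult:
    """Outcome levels recorded while sweeping one concept's initial value."""

    concept: str
    grid: np.ndarray
    homelessness_values: np.ndarray
    baseline: float
    iterations: int

    def iqr(self) -> float:
        q1, q3 = np.percentile(self.homelessness_values, [25, 75])
        return float(q3 - q1)


def sensitivity_sweep(
    cmap: ConceptMap,
    concept: str,
    grid: np.ndarray | None = None,
    baseline: float = 0.01,
    iterations: int = 3,
    outcome: str = DEFAULT_OUTCOME,
    settings: SimulationSettings | None = None,
) -> SweepResult:
    """One-at-a-time sweep of a single concept's initial value.

    For each grid value v: every concept starts at ``baseline`` except the
    outcome (0) and the swept concept (v); the map runs ``iterations`` tanh
    updates and the outcome level is recorded.
    """
    concept = normalize_concept(concept)
    outcome = normalize_concept(outcome)
    if concept == outcome:
        raise ValidationError("cannot sweep the outcome concept itself")
    c_idx = cmap.concept_index(concept)
    o_idx = cmap.concept_index(outcome)
    if grid is None:
        grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("sweep grid must be strictly increasing")
    if settings is None:
        settings = SimulationSettings(threshold="tanh", self_memory=1)

    values = np.empty_like(grid)
    for g, v in enumerate(grid):
        state = np.full(cmap.n, baseline)
        state[o_idx] = 0.0
        state[c_idx] = v
        for _ in range(iterations):
            _, state = step(state, cmap, settings)
        values[g] = state[o_idx]
    return SweepResult(
        concept=concept, grid=grid, homelessness_values=values,
        baseline=baseline, iterations=iterations,
    )


def sweep_summary(results: list[SweepResult]) -> pd.DataFrame:
    """Box-plot statistics (min, quartiles, max, IQR) per swept concept."""
    if not results:
        raise ValidationError("need at least one sweep result")
    rows = []
    for r in results:
        q1, q2, q3 = np.percentile(r.homelessness_values, [25, 50, 75])
        rows.append(
            {
                "concept": r.concept,
                "min": float(np.min(r.homelessness_values)),
                "q1": float(q1),
                "median": float(q2),
                "q3": float(q3),
                "max": float(np.max(r.homelessness_values)),
                "iqr": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)


def to_graph(cmap: ConceptMap) -> nx.DiGraph:
    """Export the weighted map as a directed graph (for GraphML viewers)."""
    g = nx.DiGraph()
    g.add_nodes_from(cmap.concepts)
    for src, tgt, w in cmap.edges():
        if src != tgt:
            g.add_edge(src, tgt, weight=w)
    return g
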