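"""Discrete dynamics of a fuzzy cognitive map.

A concept map is a signed, weighted digraph stored as an N x N matrix ``W``
with ``W[j, i]`` the weight of the edge from concept ``j`` to concept ``i``.
State vectors evolve by

    A_i(k+1) = f( sum_{j != i} A_j(k) W[j, i]  +  self_memory * A_i(k) )

where ``f`` is either the trivalent sign function (states in {-1, 0, 1}) or
the hyperbolic tangent (states in (-1, 1)). Designated concepts can be
clamped — overwritten with a fixed value after each update — to model a
sustained input. Sign-mode runs terminate on exact state repetition (a fixed
point when the repeat is immediate, otherwise a limit cycle with its period);
tanh-mode runs terminate when the largest per-concept change drops to
``epsilon`` or below.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from lingfcm.knowledge_base import ValidationError, normalize_concept


@dataclass
class ConceptMap:
    """Ordered concept names plus the signed weight matrix W (row=source)."""

    concepts: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.concepts = tuple(self.concepts)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.concepts)
        if self.W.shape != (n, n):
            raise ValidationError(
                f"weight matrix shape {self.W.shape} does not match "
                f"{n} concepts"
            )
        if not np.all(np.isfinite(self.W)):
            raise ValidationError("weight matrix contains non-finite entries")
        if np.any(np.abs(self.W) > 1 + 1e-12):
            raise ValidationError("weight magnitudes must not exceed 1")

    @property
    def n(self) -> int:
        return len(self.concepts)

    def concept_index(self, name: str) -> int:
        canonical = normalize_concept(name)
        try:
            return self.concepts.index(canonical)
        except ValueError:
            raise ValidationError(f"unknown concept {name!r}") from None

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero entries as (source, target, weight), row-major order."""
        out = []
        for j, src in enumerate(self.concepts):
            for i, tgt in enumerate(self.concepts):
                if self.W[j, i] != 0.0:
                    out.append((src, tgt, float(self.W[j, i])))
        return out


def write_map(cmap: ConceptMap, path: str | Path, decimals: int = 6) -> None:
    """Write a concept map as a delimited edge list.

    The first line records the full concept ordering (isolated concepts would
    otherwise be lost); weights are printed with fixed decimals so that
    read -> write -> read is exact at printed precision.
    """
    lines = ["# concepts: " + ";".join(cmap.concepts)]
    lines.append("source,target,signed_weight")
    for src, tgt, w in cmap.edges():
        lines.append(f"{src},{tgt},{w:.{decimals}f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_map(path: str | Path) -> ConceptMap:
    """Read a concept map written by :func:`write_map`."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    concepts: list[str] = []
    rows: list[tuple[str, str, float]] = []
    body_start = 0
    if lines and lines[0].startswith("# concepts:"):
        concepts = [c for c in lines[0].split(":", 1)[1].strip().split(";") if c]
        body_start = 1
    for ln in lines[body_start:]:
        if ln.startswith("source,"):
            continue
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 3:
            raise ValidationError(f"bad edge row: {ln!r}")
        rows.append((parts[0], parts[1], float(parts[2])))
    if not concepts:
        for src, tgt, _ in rows:
            for name in (src, tgt):
                if name not in concepts:
                    concepts.append(name)
    index = {c: i for i, c in enumerate(concepts)}
    W = np.zeros((len(concepts), len(concepts)))
    for src, tgt, w in rows:
        if src not in index or tgt not in index:
            raise ValidationError(f"edge endpoint not in concept list: {src},{tgt}")
        W[index[src], index[tgt]] = w
    return ConceptMap(tuple(concepts), W)


@dataclass
class SimulationSettings:
    """Iteration settings for :func:`simulate`.

    threshold
        ``"sign"`` for the trivalent map, ``"tanh"`` for the smooth map.
    epsilon
        Convergence tolerance on the largest per-concept change (tanh mode
        only; sign mode uses exact state repetition).
    clamp
        Mapping concept -> value held fixed after every update.
    self_memory
        0 or 1: whether a concept's own current value enters its update sum.
    """

    threshold: str = "tanh"
    epsilon: float = 1e-5
    max_iter: int = 100
    clamp: dict[str, float] = field(default_factory=dict)
    self_memory: int = 1

    def __post_init__(self) -> None:
        if self.threshold not in ("sign", "tanh"):
            raise ValidationError(f"unknown threshold {self.threshold!r}")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.self_memory not in (0, 1):
            raise ValidationError("self_memory must be 0 or 1")


@dataclass
class SimulationTrace:
    """States (initial included), raw pre-threshold sums, and termination."""

    concepts: tuple[str, ...]
    states: list[np.ndarray]
    raw_activations: list[np.ndarray]
    termination: str            # "converged" | "limit_cycle" | "max_iter"
    cycle_period: int | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def value_of(self, concept: str) -> float:
        idx = self.concepts.index(normalize_concept(concept))
        return float(self.final[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.vstack(self.states), columns=list(self.concepts)
        ).rename_axis("step")

    def metadata(self) -> dict:
        return {
            "termination": self.termination,
            "cycle_period": self.cycle_period,
            "n_states": self.n_states,
        }

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path)
        if meta_path is not None:
            Path(meta_path).write_text(
                json.dumps(self.metadata(), indent=2) + "\n", encoding="utf-8"
            )


def threshold_sign(x: float) -> int:
    """Trivalent sign function: -1 below zero, 0 at zero, +1 above."""
    if x < 0:
        return -1
    if x > 0:
        return 1
    return 0


def threshold_tanh(x: float) -> float:
    """Hyperbolic tangent, (e^{2x} - 1) / (e^{2x} + 1)."""
    return math.tanh(x)


def _apply_threshold(raw: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sign":
        return np.sign(raw)
    return np.tanh(raw)


def step(
    state: np.ndarray,
    cmap: ConceptMap,
    settings: SimulationSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """One synchronous update; returns (raw sums, thresholded next state)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (cmap.n,):
        raise ValidationError(
            f"state length {state.shape} does not match map size {cmap.n}"
        )
    off_diag = cmap.W - np.diag(np.diag(cmap.W))
    raw = state @ off_diag + settings.self_memory * state
    nxt = _apply_threshold(raw, settings.threshold)
    for concept, value in settings.clamp.items():
        nxt[cmap.concept_index(concept)] = value
    return raw, nxt


def simulate(
    cmap: ConceptMap,
    initial: Sequence[float] | np.ndarray,
    settings: SimulationSettings | None = None,
) -> SimulationTrace:
    """Iterate the map from ``initial`` until convergence, cycle, or cap.

    Sign mode stops when a state repeats an earlier one: immediate repetition
    is a fixed point ("converged"); repetition of an older state is reported
    as a limit cycle with its period. Tanh mode stops when
    ``max_i |A_i(k+1) - A_i(k)| <= epsilon``.
    """
    if settings is None:
        settings = SimulationSettings()
    state = np.asarray(initial, dtype=float).copy()
    if state.shape != (cmap.n,):
        raise ValidationError("initial state length does not match map size")

    states = [state]
    raws: list[np.ndarray] = []
    termination = "max_iter"
    period: int | None = None

    if settings.threshold == "sign":
        seen = {tuple(state.tolist()): 0}
        for _ in range(settings.max_iter):
            raw, nxt = step(states[-1], cmap, settings)
            raws.append(raw)
            states.append(nxt)
            key = tuple(nxt.tolist())
            if key in seen:
                lag = (len(states) - 1) - seen[key]
                if lag == 1:
                    termination = "converged"
                else:
                    termination, period = "limit_cycle", lag
                break
            seen[key] = len(states) - 1
    else:
        for _ in range(settings.max_iter):
            raw, nxt = step(states[-1], cmap, settings)
            if not np.all(np.isfinite(nxt)):
                raise FloatingPointError("non-finite state encountered")
            raws.append(raw)
            delta = float(np.max(np.abs(nxt - states[-1])))
            states.append(nxt)
            if delta <= settings.epsilon:
                termination = "converged"
                break

    return SimulationTrace(
        concepts=cmap.concepts,
        states=states,
        raw_activations=raws,
        termination=termination,
        cycle_period=period,
    )
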