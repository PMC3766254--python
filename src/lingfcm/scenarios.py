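"""What-if scenario runs on a weighted concept map.

A scenario activates a subset of concepts at initial levels in [0, 1] (the
outcome concept itself is never pre-activated), iterates the map under the
smooth tanh dynamics with self-memory, and classifies the converged outcome
level: saturated high (>= 0.9 by default) counts as a likely outcome,
near-zero (<= 0.1) as unlikely, anything between as uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from lingfcm.fcm_engine import (
    ConceptMap,
    SimulationSettings,
    SimulationTrace,
    simulate,
)
from lingfcm.knowledge_base import ValidationError, normalize_concept

#: Default outcome concept of the packaged map.
DEFAULT_OUTCOME = "Homelessness"


@dataclass
class ScenarioSpec:
    """Initial activations plus simulation settings for one case."""

    activations: dict[str, float]
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    label: str = ""
    outcome: str = DEFAULT_OUTCOME

    def __post_init__(self) -> None:
        outcome = normalize_concept(self.outcome)
        clean: dict[str, float] = {}
        for name, value in self.activations.items():
            canonical = normalize_concept(name)
            if canonical == outcome:
                raise ValidationError(
                    f"outcome concept {outcome!r} must not be pre-activated"
                )
            v = float(value)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"activation for {name!r} outside [0, 1]: {v}"
                )
            clean[canonical] = v
        self.activations = clean
        self.outcome = outcome

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        settings = SimulationSettings(**payload.get("settings", {}))
        return cls(
            activations=payload["activations"],
            settings=settings,
            label=payload.get("label", Path(path).stem),
            outcome=payload.get("outcome", DEFAULT_OUTCOME),
        )

    def initial_state(self, cmap: ConceptMap) -> np.ndarray:
        state = np.zeros(cmap.n)
        for name, value in self.activations.items():
            state[cmap.concept_index(name)] = value
        return state


@dataclass
class OutcomeClassification:
    """Category of a finished run plus its trajectory summary."""

    label: str
    category: str               # likely | unlikely | uncertain
    final_level: float
    trajectory_summary: "object"   # DataFrame: per-concept min/max/final

    CATEGORIES = ("likely_homelessness", "unlikely_homelessness", "uncertain")


def classify_outcome(
    trace: SimulationTrace,
    outcome: str = DEFAULT_OUTCOME,
    label: str = "",
    high: float = 0.9,
    low: float = 0.1,
) -> OutcomeClassification:
    """Classify by the outcome concept's final level against thresholds."""
    import pandas as pd

    final_level = trace.value_of(outcome)
    if final_level >= high:
        category = "likely_homelessness"
    elif final_level <= low:
        category = "unlikely_homelessness"
    else:
        category = "uncertain"
    frame = trace.to_frame()
    summary = pd.DataFrame(
        {"min": frame.min(), "max": frame.max(), "final": frame.iloc[-1]}
    ).rename_axis("concept")
    return OutcomeClassification(
        label=label, category=category, final_level=final_level,
        trajectory_summary=summary,
    )


def run_case(
    cmap: ConceptMap,
    spec: ScenarioSpec,
    high: float = 0.9,
    low: float = 0.1,
) -> tuple[SimulationTrace, OutcomeClassification]:
    """Simulate one scenario and classify its outcome."""
    trace = simulate(cmap, spec.initial_state(cmap), spec.settings)
    return trace, classify_outcome(
        trace, outcome=spec.outcome, label=spec.label, high=high, low=low
    )


def compare_cases(results: list[OutcomeClassification]) -> "object":
    """Order finished cases by final outcome level (highest first).

    Returns a DataFrame with rank, label, final level, and category; exact
    ties share a rank.
    """
    import pandas as pd

    if not results:
        raise ValidationError("need at least one result to compare")
    frame = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "final_level": [r.final_level for r in results],
            "category": [r.category for r in results],
        }
    )
    frame = frame.sort_values(
        "final_level", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = (
        frame["final_level"].rank(method="min", ascending=False).astype(int)
    )
    return frame[["rank", "label", "final_level", "category"]]
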