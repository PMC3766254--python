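"""Loaders for the packaged fixtures.

Ships: the 14-concept / 31-edge homelessness knowledge base and term lexicon
transcribed from the source literature review, the six-concept heart-disease
teaching map used to validate the sign-mode engine, and the three prototype
scenario configurations.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from lingfcm.fcm_engine import ConceptMap, read_map
from lingfcm.fuzzy_inference import FuzzyPartition, weight_matrix
from lingfcm.knowledge_base import (
    HOMELESSNESS_CONCEPTS,
    KnowledgeBase,
    TermLexicon,
    read_knowledge_base,
    read_lexicon,
)


def _data_path(*parts: str) -> Path:
    return Path(resources.files("lingfcm").joinpath("data", *parts))  # type: ignore[arg-type]


def load_knowledge_base() -> KnowledgeBase:
    """The packaged homelessness evidence base (14 concepts, 31 edges)."""
    return read_knowledge_base(
        _data_path("homelessness_knowledge_base.csv"),
        concepts=HOMELESSNESS_CONCEPTS,
    )


def load_lexicon() -> TermLexicon:
    """The packaged phrase -> level word bank."""
    return read_lexicon(_data_path("term_lexicon.csv"))


def load_heart_disease_map() -> ConceptMap:
    """Six-concept exercise/heart-disease map with {-1, 0, 1} weights."""
    return read_map(_data_path("heart_disease_map.csv"))


def load_homelessness_map(partition: FuzzyPartition | None = None) -> ConceptMap:
    """The FIS-weighted homelessness map (weights computed, not stored)."""
    return weight_matrix(load_knowledge_base(), partition)


def scenario_path(case: str) -> Path:
    """Path of a packaged scenario config: "case1", "case2", or "case3"."""
    path = _data_path("scenarios", f"{case}.yaml")
    if not path.exists():
        raise FileNotFoundError(f"no packaged scenario named {case!r}")
    return path
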