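"""Linguistic knowledge base: concepts, evidence edges, and the term lexicon.

The evidence base is a list of directed influences between named concepts.
Each influence carries a sign (+1 stressor / -1 protective) and exactly three
ordinal linguistic levels, one per supporting source, on the five-level scale
VL < L < M < H < VH. The lexicon maps the verbatim phrases found in the
literature (``"profound"``, ``"did not predict"`` ...) to those levels.

Concept naming is normalised: the packaged homelessness map is referred to in
different places by abbreviations ("CJS", "NGO") and drifted labels ("Social
Systems Network" vs "Social Support Network"); every variant resolves to one
canonical name.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ValidationError(ValueError):
    """Raised when a knowledge base, lexicon, or map fails validation."""


@enum.unique
class LinguisticLevel(enum.IntEnum):
    """Five-level ordinal scale for linguistic strength judgements."""

    VL = 1
    L = 2
    M = 3
    H = 4
    VH = 5

    @classmethod
    def from_code(cls, code: str) -> "LinguisticLevel":
        """Parse a level from a short code or long form ("Very high")."""
        token = code.strip().lower().replace("-", " ")
        table = {
            "vl": cls.VL, "very low": cls.VL,
            "l": cls.L, "low": cls.L,
            "m": cls.M, "medium": cls.M,
            "h": cls.H, "high": cls.H,
            "vh": cls.VH, "very high": cls.VH,
        }
        try:
            return table[token]
        except KeyError:
            raise ValidationError(f"unknown linguistic level {code!r}") from None

    def mirror(self) -> "LinguisticLevel":
        """Reflection about the scale midpoint: VL<->VH, L<->H, M->M."""
        return LinguisticLevel(6 - self.value)


#: Canonical concept names of the packaged homelessness map, in printed
#: index order (1-based indices 1..14).
HOMELESSNESS_CONCEPTS: tuple[str, ...] = (
    "Homelessness",
    "Criminal Justice System Involvement",
    "Poverty",
    "Unemployment",
    "Education",
    "Income",
    "Addiction",
    "Social Support Network",
    "Family Breakdown",
    "Mental Illness",
    "Non-Government Assistance",
    "Childhood Homelessness",
    "Government Assistance",
    "Cost of Housing",
)

#: Label variants seen across the source tables and figures, lower-cased.
_CONCEPT_ALIASES: dict[str, str] = {
    "cjs": "Criminal Justice System Involvement",
    "criminal justice system": "Criminal Justice System Involvement",
    "criminal justice system involvement": "Criminal Justice System Involvement",
    "social systems network": "Social Support Network",
    "social support network": "Social Support Network",
    "social network support": "Social Support Network",
    "social network": "Social Support Network",
    "ngo": "Non-Government Assistance",
    "non-government assistance": "Non-Government Assistance",
    "non government assistance": "Non-Government Assistance",
    "non-government organization": "Non-Government Assistance",
    "childhood homelessness": "Childhood Homelessness",
    "childhood hardships": "Childhood Homelessness",
    "family breakdown": "Family Breakdown",
    "mental illness": "Mental Illness",
    "government assistance": "Government Assistance",
    "cost of housing": "Cost of Housing",
    "homelessness": "Homelessness",
    "poverty": "Poverty",
    "unemployment": "Unemployment",
    "education": "Education",
    "income": "Income",
    "addiction": "Addiction",
    "addictions": "Addiction",
}


def normalize_concept(name: str) -> str:
    """Resolve a concept label variant to its canonical name.

    Unknown names are returned trimmed but otherwise untouched, so synthetic
    maps with arbitrary concept names pass through unchanged.
    """
    key = name.strip().lower()
    return _CONCEPT_ALIASES.get(key, name.strip())


@dataclass(frozen=True)
class EdgeEvidence:
    """One directed influence with its sign and three linguistic levels."""

    source: str
    target: str
    sign: int
    levels: tuple[LinguisticLevel, LinguisticLevel, LinguisticLevel]
    citations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError(
                f"self-influence {self.source!r} -> {self.target!r} is not allowed"
            )
        if self.sign not in (+1, -1):
            raise ValidationError(f"sign must be +1 or -1, got {self.sign!r}")
        if len(self.levels) != 3:
            raise ValidationError(
                f"expected 3 linguistic levels for {self.source!r} -> "
                f"{self.target!r}, got {len(self.levels)}"
            )


@dataclass
class TermLexicon:
    """Closed word bank mapping lower-cased phrases to linguistic levels."""

    entries: dict[str, LinguisticLevel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, phrase: str) -> bool:
        return _normalize_phrase(phrase) in self.entries

    def lookup(self, phrase: str) -> LinguisticLevel:
        key = _normalize_phrase(phrase)
        try:
            return self.entries[key]
        except KeyError:
            raise ValidationError(f"unclassified term: {phrase!r}") from None

    def add(self, phrase: str, level: LinguisticLevel) -> None:
        key = _normalize_phrase(phrase)
        if key in self.entries and self.entries[key] != level:
            raise ValidationError(
                f"phrase {phrase!r} already classified as "
                f"{self.entries[key].name}"
            )
        self.entries[key] = level


def _normalize_phrase(phrase: str) -> str:
    return " ".join(phrase.strip().lower().split())


def lookup_level(phrase: str, lexicon: TermLexicon) -> LinguisticLevel:
    """Return the lexicon's level for an exact (case-folded) phrase."""
    return lexicon.lookup(phrase)


@dataclass
class KnowledgeBase:
    """Ordered concept list plus the evidence edges between concepts."""

    concepts: tuple[str, ...]
    edges: tuple[EdgeEvidence, ...]

    def __post_init__(self) -> None:
        if len(set(self.concepts)) != len(self.concepts):
            raise ValidationError("duplicate concept names")
        known = set(self.concepts)
        seen_pairs: set[tuple[str, str]] = set()
        for i, e in enumerate(self.edges):
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    raise ValidationError(
                        f"edge {i}: unknown concept {endpoint!r}"
                    )
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise ValidationError(f"edge {i}: duplicate edge {pair!r}")
            seen_pairs.add(pair)

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def concept_index(self, name: str) -> int:
        canonical = normalize_concept(name)
        try:
            return self.concepts.index(canonical)
        except ValueError:
            raise ValidationError(f"unknown concept {name!r}") from None


def evidence_counts(kb: KnowledgeBase) -> dict[str, int]:
    """Summary counts: edges, concepts, and total linguistic terms (3/edge)."""
    return {
        "n_edges": kb.n_edges,
        "n_concepts": kb.n_concepts,
        "n_terms": 3 * kb.n_edges,
    }


_KB_COLUMNS = (
    "source_id", "source_name", "target_id", "target_name",
    "sign", "level1", "level2", "level3", "refs",
)


def parse_knowledge_base(
    records: Iterable[Mapping[str, str]],
    concepts: Sequence[str] | None = None,
) -> KnowledgeBase:
    """Build a validated knowledge base from tabular rows.

    Each row must carry ``source_name``, ``target_name``, ``sign`` (``+``/``-``),
    and ``level1``..``level3``; ``refs`` is an optional ``;``-separated list of
    citation tags. Concept names are normalised through the alias table. When
    ``concepts`` is not given, the concept list is inferred from ``source_id``/
    ``target_id`` columns (printed 1-based indices) or, failing that, from
    first appearance order.
    """
    rows = list(records)
    edges: list[EdgeEvidence] = []
    indexed: dict[int, str] = {}
    appearance: list[str] = []

    for rownum, row in enumerate(rows, start=1):
        try:
            source = normalize_concept(row["source_name"])
            target = normalize_concept(row["target_name"])
            sign_token = str(row["sign"]).strip()
            level_codes = [row["level1"], row["level2"], row["level3"]]
        except KeyError as exc:
            raise ValidationError(f"row {rownum}: missing column {exc}") from None
        for code in level_codes:
            if not str(code).strip():
                raise ValidationError(
                    f"row {rownum}: expected 3 linguistic levels"
                )
        if sign_token in ("+", "+1", "1", "positive", "Positive"):
            sign = +1
        elif sign_token in ("-", "-1", "negative", "Negative"):
            sign = -1
        else:
            raise ValidationError(f"row {rownum}: bad sign {sign_token!r}")
        levels = tuple(LinguisticLevel.from_code(c) for c in level_codes)
        refs = tuple(
            t.strip() for t in str(row.get("refs", "")).split(";") if t.strip()
        )
        try:
            edge = EdgeEvidence(source, target, sign, levels, refs)  # type: ignore[arg-type]
        except ValidationError as exc:
            raise ValidationError(f"row {rownum}: {exc}") from None
        edges.append(edge)
        for name, id_col in ((source, "source_id"), (target, "target_id")):
            if name not in appearance:
                appearance.append(name)
            raw_id = str(row.get(id_col, "")).strip()
            if raw_id:
                idx = int(raw_id)
                if indexed.get(idx, name) != name:
                    raise ValidationError(
                        f"row {rownum}: index {idx} bound to both "
                        f"{indexed[idx]!r} and {name!r}"
                    )
                indexed[idx] = name

    if concepts is not None:
        ordered = tuple(normalize_concept(c) for c in concepts)
    elif indexed:
        ordered = tuple(indexed[i] for i in sorted(indexed))
        # keep any concepts that only ever appeared without an index
        extra = tuple(c for c in appearance if c not in ordered)
        ordered = ordered + extra
    else:
        ordered = tuple(appearance)

    try:
        return KnowledgeBase(concepts=ordered, edges=tuple(edges))
    except ValidationError as exc:
        raise ValidationError(str(exc)) from None


def read_knowledge_base(
    path: str | Path, concepts: Sequence[str] | None = None
) -> KnowledgeBase:
    """Read a knowledge base from its CSV serialisation."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return parse_knowledge_base(list(reader), concepts=concepts)


def write_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a knowledge base to CSV (round-trips through the reader)."""
    index_of = {name: i + 1 for i, name in enumerate(kb.concepts)}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_KB_COLUMNS)
        writer.writeheader()
        for e in kb.edges:
            writer.writerow({
                "source_id": index_of[e.source],
                "source_name": e.source,
                "target_id": index_of[e.target],
                "target_name": e.target,
                "sign": "+" if e.sign > 0 else "-",
                "level1": e.levels[0].name,
                "level2": e.levels[1].name,
                "level3": e.levels[2].name,
                "refs": ";".join(e.citations),
            })


def dumps_knowledge_base(kb: KnowledgeBase) -> str:
    """Serialise a knowledge base to a CSV string."""
    buf = io.StringIO()
    index_of = {name: i + 1 for i, name in enumerate(kb.concepts)}
    writer = csv.DictWriter(buf, fieldnames=_KB_COLUMNS)
    writer.writeheader()
    for e in kb.edges:
        writer.writerow({
            "source_id": index_of[e.source],
            "source_name": e.source,
            "target_id": index_of[e.target],
            "target_name": e.target,
            "sign": "+" if e.sign > 0 else "-",
            "level1": e.levels[0].name,
            "level2": e.levels[1].name,
            "level3": e.levels[2].name,
            "refs": ";".join(e.citations),
        })
    return buf.getvalue()


def read_lexicon(path: str | Path) -> TermLexicon:
    """Read a phrase -> level lexicon from a two-column CSV."""
    lexicon = TermLexicon()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            lexicon.add(row["phrase"], LinguisticLevel.from_code(row["level"]))
    return lexicon


def write_lexicon(lexicon: TermLexicon, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phrase", "level"])
        for phrase, level in lexicon.entries.items():
            writer.writerow([phrase, level.name])
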