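"""Synonym ontology backing the pairwise token similarity sim[i][j].

General-purpose Chinese semantic resources (HowNet) miss most medical
terms, and no open Chinese equivalent of UMLS/SNOMED-CT exists, so the
semantic LCS relies on a domain synonym knowledge base: groups of
interchangeable terms ("hepatitis B" ~ "serum hepatitis"), each group
carrying a within-group similarity weight in (0, 1].

Token similarity is the maximum of three evidence sources:

* exact surface equality            -> 1.0
* shared synonym group              -> the group weight (max over groups)
* optional character-bigram Dice    -> catches small spelling variants

With an empty ontology and the fallback off, similarity degenerates to the
exact-match indicator, i.e. the plain word-matching regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .tokenizer import Token, normalize

__all__ = ["SynonymGroup", "TermOntology", "token_similarity", "load_ontology",
           "OntologyFormatError", "character_dice"]


class OntologyFormatError(ValueError):
    """Raised for malformed or invalid ontology files."""


@dataclass(frozen=True)
class SynonymGroup:
    """A set of interchangeable term surfaces sharing one similarity weight."""

    concept_id: str
    members: frozenset[str]
    weight: float = 0.9

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.concept_id!r} has no members")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(
                f"group {self.concept_id!r}: weight must be in (0, 1], got {self.weight}"
            )


@dataclass(frozen=True)
class TermOntology:
    """Synonym groups plus a character-similarity fallback switch.

    A surface may belong to several groups; lookups take the maximum weight
    over shared groups.  No transitive closure is applied across groups.
    """

    groups: tuple[SynonymGroup, ...] = ()
    fallback: bool = False

    def __post_init__(self) -> None:
        index: dict[str, list[tuple[int, float]]] = {}
        for gi, g in enumerate(self.groups):
            for m in g.members:
                index.setdefault(normalize(m), []).append((gi, g.weight))
        object.__setattr__(self, "_index", index)
        # memo over normalized surface pairs; libraries re-score the same
        # token pairs thousands of times during a full-SDL scan
        object.__setattr__(self, "_memo", {})

    def group_weight(self, a: str, b: str) -> float:
        """Maximum weight of a synonym group containing both surfaces, else 0."""
        index: dict[str, list[tuple[int, float]]] = getattr(self, "_index")
        ga = index.get(normalize(a))
        gb = index.get(normalize(b))
        if not ga or not gb:
            return 0.0
        ids_b = {gi: w for gi, w in gb}
        best = 0.0
        for gi, w in ga:
            if gi in ids_b:
                best = max(best, w)
        return best


EMPTY_ONTOLOGY = TermOntology()


def _bigrams(s: str) -> set[str]:
    if len(s) < 2:
        return {s}
    return {s[i : i + 2] for i in range(len(s) - 1)}


def character_dice(a: str, b: str) -> float:
    """Dice coefficient of the character-bigram sets of two surfaces."""
    ba, bb = _bigrams(a), _bigrams(b)
    if not ba and not bb:
        return 0.0
    return 2.0 * len(ba & bb) / (len(ba) + len(bb))


def token_similarity(a: Token | str, b: Token | str, onto: TermOntology = EMPTY_ONTOLOGY) -> float:
    """Pairwise token similarity in [0, 1]; symmetric; 1 on identical surfaces."""
    sa = normalize(a.surface if isinstance(a, Token) else a)
    sb = normalize(b.surface if isinstance(b, Token) else b)
    if sa == sb:
        return 1.0
    memo: dict[tuple[str, str], float] = getattr(onto, "_memo")
    key = (sa, sb) if sa <= sb else (sb, sa)
    sim = memo.get(key)
    if sim is None:
        sim = onto.group_weight(sa, sb)
        if onto.fallback:
            sim = max(sim, character_dice(sa, sb))
        memo[key] = sim
    return sim


def load_ontology(path: str | Path, fallback: bool = False) -> TermOntology:
    """Load a TSV (``id<TAB>weight<TAB>m1|m2|...``) or JSON ontology file.

    JSON files hold a list of ``{"id": ..., "weight": ..., "members": [...]}``
    objects.  Duplicate concept ids and weights outside (0, 1] are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        groups = _load_json(path)
    else:
        groups = _load_tsv(path)
    seen: set[str] = set()
    for g in groups:
        if g.concept_id in seen:
            raise OntologyFormatError(f"{path}: duplicate concept id {g.concept_id!r}")
        seen.add(g.concept_id)
    return TermOntology(groups=tuple(groups), fallback=fallback)


def _make_group(concept_id: str, weight: float, members: list[str], where: str) -> SynonymGroup:
    try:
        return SynonymGroup(
            concept_id=concept_id,
            members=frozenset(m.strip() for m in members if m.strip()),
            weight=weight,
        )
    except ValueError as exc:
        raise OntologyFormatError(f"{where}: {exc}") from exc


def _load_tsv(path: Path) -> list[SynonymGroup]:
    groups: list[SynonymGroup] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise OntologyFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            cid, weight_s, members_s = parts
            try:
                weight = float(weight_s)
            except ValueError as exc:
                raise OntologyFormatError(
                    f"{path}:{lineno}: weight is not a number: {weight_s!r}"
                ) from exc
            groups.append(
                _make_group(cid.strip(), weight, members_s.split("|"), f"{path}:{lineno}")
            )
    return groups


def _load_json(path: Path) -> list[SynonymGroup]:
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OntologyFormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise OntologyFormatError(f"{path}: expected a JSON list of groups")
    groups = []
    for i, obj in enumerate(data):
        if not isinstance(obj, dict) or not {"id", "weight", "members"} <= set(obj):
            raise OntologyFormatError(
                f"{path}: entry {i} must be an object with id/weight/members"
            )
        groups.append(
            _make_group(str(obj["id"]), float(obj["weight"]), list(obj["members"]),
                        f"{path}: entry {i}")
        )
    return groups
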