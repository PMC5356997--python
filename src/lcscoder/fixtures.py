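"""Bundled worked examples and synthetic benchmark generation.

Two kinds of test data, so every other module is exercisable without any
external download:

* The published worked examples: a four-entry hepatitis-A slice of the
  standard diagnosis library (pinyin-transcribed), the abbreviated query
  "JIA GAN BAN GAN HUN MI" whose gold code is B15.000, the segmentation
  example, and the 30-row table of (L(A), L(B), LCSL) similarity triples
  with their printed values.  Each table row carries a consistency flag:
  the rows with L(A) in {5, 6} do not agree with the printed formulas and
  are treated as typographical, so they are excluded from regression.

* A synthetic benchmark generator emulating the structure of the real SDL:
  diagnosis names composed as modifier* + disease-root + complication?,
  a synonym ontology over part of the vocabulary (standing in for a
  disease ontology of synonym groups), and queries perturbed the way
  clinicians actually deviate from standard names — synonym substitutions,
  dropped or inserted tokens, small spelling mistakes, abbreviations.
  Perturbations never touch the disease-root token, so the gold code stays
  recoverable by construction.  All generation is a pure function of the
  parameters and the seed.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path

from .coder import StandardDiagnosisLibrary, build_sdl
from .ontology import SynonymGroup, TermOntology
from .similarity import lcs_similarity, round2, tlcs_similarity, wlcs_similarity
from .tokenizer import SegmenterConfig

__all__ = [
    "Table3Row",
    "PaperFixtures",
    "paper_fixtures",
    "PerturbationSpec",
    "SyntheticBenchmark",
    "generate_benchmark",
    "PERTURBATION_OPS",
]

# --------------------------------------------------------------------------
# Published worked examples (pinyin transcription)
# --------------------------------------------------------------------------

TABLE1_ROWS: tuple[tuple[str, str, str], ...] = (
    ("JIA XING BING DU XING GAN YAN BAN GAN HUN MI",
     "B15.000", "hepatitis A with hepatic coma"),
    ("JI XING JIA XING BING DU XING GAN YAN BAN GAN HUN MI",
     "B15.001", "acute hepatitis A with hepatic coma"),
    ("JI XING ZHONG XING JIA XING BING DU XING GAN YAN BAN GAN HUN MI",
     "B15.002", "acute severe hepatitis A with hepatic coma"),
    ("YA JI XING ZHONG XING JIA XING BING DU XING GAN YAN BAN GAN HUN MI",
     "B15.003", "subacute severe hepatitis A with hepatic coma"),
)

#: Lexicon sufficient to segment the bundled examples the published way.
FIXTURE_LEXICON: frozenset[str] = frozenset({
    "JIA XING",
    "BING DU XING GAN YAN",
    "GAN HUN MI",
    "JI XING",
    "YA JI XING",
    "ZHONG XING",
    "JIA GAN",
    "BU BAN",
})

FIXTURE_STOP_WORDS: frozenset[str] = frozenset({"BAN", "BU BAN"})
FIXTURE_NEGATION_WORDS: frozenset[str] = frozenset({"BU BAN"})

#: Printed similarity table: (la, lb, lcsl, lcs, tlcs, wlcs).
TABLE3_PRINTED: tuple[tuple[int, int, int, float, float, float], ...] = (
    (1, 1, 1, 1.00, 1.00, 1.00),
    (1, 2, 1, 0.50, 0.67, 0.67),
    (1, 3, 1, 0.33, 0.50, 0.50),
    (1, 4, 1, 0.25, 0.40, 0.40),
    (1, 5, 1, 0.20, 0.33, 0.33),
    (2, 2, 2, 1.00, 1.00, 1.00),
    (2, 3, 2, 0.67, 0.80, 0.86),
    (2, 4, 2, 0.50, 0.67, 0.75),
    (2, 5, 2, 0.40, 0.57, 0.67),
    (2, 6, 2, 0.33, 0.50, 0.60),
    (3, 3, 3, 1.00, 1.00, 1.00),
    (3, 4, 3, 0.75, 0.86, 0.92),
    (3, 5, 3, 0.60, 0.75, 0.86),
    (3, 6, 3, 0.50, 0.67, 0.80),
    (3, 7, 3, 0.43, 0.60, 0.75),
    (4, 4, 4, 1.00, 1.00, 1.00),
    (4, 5, 4, 0.80, 0.89, 0.95),
    (4, 6, 4, 0.67, 0.80, 0.91),
    (4, 7, 4, 0.57, 0.73, 0.87),
    (4, 8, 4, 0.50, 0.67, 0.83),
    (5, 5, 5, 1.00, 1.00, 1.00),
    (5, 6, 5, 0.81, 0.90, 0.92),
    (5, 7, 5, 0.75, 0.82, 0.90),
    (5, 8, 5, 0.67, 0.82, 0.87),
    (5, 9, 5, 0.55, 0.68, 0.84),
    (6, 6, 6, 1.00, 1.00, 1.00),
    (6, 7, 6, 0.80, 0.85, 0.91),
    (6, 8, 6, 0.71, 0.76, 0.83),
    (6, 9, 6, 0.66, 0.72, 0.78),
    (6, 10, 6, 0.60, 0.65, 0.70),
)


@dataclass(frozen=True)
class Table3Row:
    la: int
    lb: int
    lcsl: int
    lcs: float
    tlcs: float
    wlcs: float
    consistent: bool  # printed values agree with the formulas at 2 decimals


def _table3_rows() -> tuple[Table3Row, ...]:
    rows = []
    for la, lb, lcsl, p_lcs, p_tlcs, p_wlcs in TABLE3_PRINTED:
        consistent = (
            round2(lcs_similarity(lcsl, la, lb).value) == p_lcs
            and round2(tlcs_similarity(lcsl, la, lb).value) == p_tlcs
            and round2(wlcs_similarity(lcsl, la, lb).value) == p_wlcs
        )
        rows.append(Table3Row(la, lb, lcsl, p_lcs, p_tlcs, p_wlcs, consistent))
    return tuple(rows)


def fixture_config(mode: str = "token") -> SegmenterConfig:
    return SegmenterConfig(
        lexicon=FIXTURE_LEXICON,
        stop_words=FIXTURE_STOP_WORDS,
        negation_words=FIXTURE_NEGATION_WORDS,
        mode=mode,
    )


def fixture_ontology(weight: float = 0.9, fallback: bool = False) -> TermOntology:
    """Synonym group linking the abbreviation "JIA GAN" (hep A) with the
    standard modifier + disease tokens it abbreviates."""
    return TermOntology(
        groups=(
            SynonymGroup(
                concept_id="hepatitis-a",
                members=frozenset({"JIA GAN", "JIA XING", "BING DU XING GAN YAN"}),
                weight=weight,
            ),
        ),
        fallback=fallback,
    )


@dataclass(frozen=True)
class PaperFixtures:
    sdl: StandardDiagnosisLibrary
    ontology: TermOntology
    config: SegmenterConfig
    abbreviated_query: str
    abbreviated_gold: str
    segmentation_example: str
    segmentation_tokens: tuple[str, ...]       # after segmentation
    filtered_tokens: tuple[str, ...]           # after stop-word filtration
    negation_example: str
    table3: tuple[Table3Row, ...]


def paper_fixtures() -> PaperFixtures:
    """The bundled worked examples as ready-built objects."""
    config = fixture_config()
    sdl = build_sdl([(name, code) for name, code, _ in TABLE1_ROWS], config)
    return PaperFixtures(
        sdl=sdl,
        ontology=fixture_ontology(),
        config=config,
        abbreviated_query="JIA GAN BAN GAN HUN MI",
        abbreviated_gold="B15.000",
        segmentation_example=TABLE1_ROWS[0][0],
        segmentation_tokens=("jia xing", "bing du xing gan yan", "ban", "gan hun mi"),
        filtered_tokens=("jia xing", "bing du xing gan yan", "gan hun mi"),
        negation_example="JIA XING BING DU XING GAN YAN BU BAN GAN HUN MI",
        table3=_table3_rows(),
    )


# --------------------------------------------------------------------------
# Synthetic benchmark generation
# --------------------------------------------------------------------------

PERTURBATION_OPS = ("synonym_swap", "token_drop", "token_insert", "char_typo", "abbreviation")

_ONSETS = ("b", "ch", "d", "f", "g", "h", "j", "k", "l", "m",
           "n", "p", "q", "r", "s", "sh", "t", "w", "x", "zh")
_RIMES = ("a", "ai", "an", "ang", "ao", "e", "en", "eng", "i",
          "ia", "ie", "in", "ing", "iu", "o", "ong", "ou", "u", "ue", "un")


@dataclass(frozen=True)
class PerturbationSpec:
    """Which corruption operations to apply to a query, and with what seed."""

    ops: tuple[str, ...] = ("synonym_swap",)
    seed: int = 0

    def __post_init__(self) -> None:
        for op in self.ops:
            if op not in PERTURBATION_OPS:
                raise ValueError(f"unknown perturbation op {op!r}")


@dataclass(frozen=True)
class SyntheticBenchmark:
    sdl: StandardDiagnosisLibrary
    ontology: TermOntology
    config: SegmenterConfig
    queries: tuple[tuple[str, str, PerturbationSpec], ...]  # (text, gold code, spec)
    vocabulary: tuple[str, ...]
    seed: int

    def write(self, outdir: str | Path) -> None:
        """Write sdl.tsv, ontology.tsv, lexicon.txt, stopwords.txt, queries.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "sdl.tsv", "w", encoding="utf-8") as fh:
            for e in self.sdl.entries:
                fh.write(f"{e.name}\t{e.code}\n")
        with open(outdir / "ontology.tsv", "w", encoding="utf-8") as fh:
            for g in self.ontology.groups:
                members = "|".join(sorted(g.members))
                fh.write(f"{g.concept_id}\t{g.weight}\t{members}\n")
        with open(outdir / "lexicon.txt", "w", encoding="utf-8") as fh:
            for w in self.vocabulary:
                fh.write(w + "\n")
        with open(outdir / "stopwords.txt", "w", encoding="utf-8") as fh:
            fh.write("# no stop words in the synthetic benchmark\n")
        with open(outdir / "queries.tsv", "w", encoding="utf-8") as fh:
            for text, gold, _ in self.queries:
                fh.write(f"{text}\t{gold}\n")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_RIMES)


def _word(rng: random.Random, existing: set[str]) -> str:
    while True:
        w = "".join(_syllable(rng) for _ in range(rng.randint(2, 3))).upper()
        if w not in existing:
            existing.add(w)
            return w


def _code(k: int) -> str:
    letter = chr(ord("A") + (k // 100000) % 26)
    return f"{letter}{(k // 1000) % 100:02d}.{k % 1000:03d}"


def generate_benchmark(
    n_codes: int = 50,
    n_queries: int = 100,
    vocab_size: int = 40,
    spec: PerturbationSpec = PerturbationSpec(),
    seed: int = 0,
    synonym_fraction: float = 0.3,
    group_weight: float = 0.9,
    fallback: bool = False,
) -> SyntheticBenchmark:
    """Build a reproducible synthetic SDL + ontology + perturbed query set.

    Diagnosis names are 2–8 token compositions ``modifier* root complication?``
    over a pinyin-like ASCII vocabulary.  ``synonym_fraction`` of the
    vocabulary receives an out-of-vocabulary alias in a weight-``group_weight``
    synonym group; the ``synonym_swap`` perturbation substitutes those
    aliases.  An empty ``spec.ops`` leaves queries identical to their
    standard names.
    """
    if n_codes < 1 or n_queries < 1:
        raise ValueError("n_codes and n_queries must be >= 1")
    if vocab_size < 10:
        raise ValueError("vocab_size must be >= 10")
    if not 0.0 <= synonym_fraction <= 1.0:
        raise ValueError("synonym_fraction must be in [0, 1]")
    rng = random.Random(seed)

    existing: set[str] = set()
    vocab = [_word(rng, existing) for _ in range(vocab_size)]
    n_roots = max(2, vocab_size // 4)
    n_compl = max(2, vocab_size // 5)
    roots = vocab[:n_roots]
    complications = vocab[n_roots : n_roots + n_compl]
    modifiers = vocab[n_roots + n_compl :] or vocab[:2]

    # Synonym aliases for a slice of the vocabulary (aliases are OOV words).
    n_syn = round(len(vocab) * synonym_fraction)
    syn_words = rng.sample(vocab, n_syn) if n_syn else []
    alias_of: dict[str, str] = {}
    groups: list[SynonymGroup] = []
    for gi, w in enumerate(sorted(syn_words)):
        alias = _word(rng, existing)
        alias_of[w] = alias
        groups.append(
            SynonymGroup(
                concept_id=f"syn{gi:04d}",
                members=frozenset({w, alias}),
                weight=group_weight,
            )
        )
    ontology = TermOntology(groups=tuple(groups), fallback=fallback)

    # Unique diagnosis names: modifier* + root + optional complication.
    names: list[tuple[str, ...]] = []
    seen_names: set[tuple[str, ...]] = set()
    while len(names) < n_codes:
        n_mod = rng.randint(0, 3)
        toks = tuple(rng.sample(modifiers, min(n_mod, len(modifiers)))) + (rng.choice(roots),)
        if rng.random() < 0.5:
            toks = toks + (rng.choice(complications),)
        if toks not in seen_names:
            seen_names.add(toks)
            names.append(toks)
    config = SegmenterConfig(lexicon=frozenset(vocab) | frozenset(alias_of.values()))
    rows = [(" ".join(toks), _code(k)) for k, toks in enumerate(names)]
    sdl = build_sdl(rows, config)
    root_of = {row[1]: names[k][-1] if names[k][-1] in roots else names[k][-2]
               for k, row in enumerate(rows)}

    queries: list[tuple[str, str, PerturbationSpec]] = []
    for _ in range(n_queries):
        k = rng.randrange(n_codes)
        name_tokens = list(names[k])
        gold = rows[k][1]
        qseed = rng.randrange(2**31)
        qspec = PerturbationSpec(ops=spec.ops, seed=qseed)
        perturbed = _perturb(name_tokens, qspec, alias_of, vocab, root_of[gold])
        queries.append((" ".join(perturbed), gold, qspec))

    return SyntheticBenchmark(
        sdl=sdl,
        ontology=ontology,
        config=config,
        queries=tuple(queries),
        vocabulary=tuple(sorted(frozenset(vocab) | frozenset(alias_of.values()))),
        seed=seed,
    )


def _perturb(
    tokens: list[str],
    spec: PerturbationSpec,
    alias_of: dict[str, str],
    vocab: list[str],
    root: str,
) -> list[str]:
    """Apply each op in ``spec.ops`` once; the disease root is never altered."""
    rng = random.Random(spec.seed)
    out = list(tokens)
    for op in spec.ops:
        non_root = [i for i, t in enumerate(out) if t != root]
        if op == "synonym_swap":
            swappable = [i for i, t in enumerate(out) if t in alias_of]
            if swappable:
                i = rng.choice(swappable)
                out[i] = alias_of[out[i]]
        elif op == "token_drop":
            if non_root and len(out) > 1:
                del out[rng.choice(non_root)]
        elif op == "token_insert":
            out.insert(rng.randint(0, len(out)), rng.choice(vocab))
        elif op == "char_typo":
            if non_root:
                i = rng.choice(non_root)
                w = out[i]
                pos = rng.randrange(len(w))
                repl = rng.choice(string.ascii_uppercase.replace(w[pos], "A" if w[pos] != "A" else "B"))
                out[i] = w[:pos] + repl + w[pos + 1 :]
        elif op == "abbreviation":
            candidates = [i for i in non_root if len(out[i]) >= 4]
            if candidates:
                i = rng.choice(candidates)
                out[i] = out[i][: max(2, len(out[i]) // 2)]
    return out
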