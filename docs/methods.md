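# Methods

## Model

The coder treats ICD-10 assignment as nearest-neighbour retrieval over a
standard diagnosis library (SDL) under a sequence similarity. Both the
query and every library entry are segmented into word (token) sequences;
similarity is computed from the length of their longest common subsequence
(LCS), with the token-match test generalized from surface equality to a
semantic threshold:

    c[i][j] = 0                                   if i = 0 or j = 0
    c[i][j] = c[i-1][j-1] + 1                     if sim(a_i, b_j) > ε
    c[i][j] = max(c[i-1][j], c[i][j-1])           otherwise

The two non-base branches are exclusive (`if sim > ε … else max`), so the
recurrence is exhaustive even when tokens are unequal but dissimilar. The
threshold test is strict `>` by default; an inclusive `>=` mode is provided
(`inclusive=True` / `--epsilon-inclusive`) because both conventions appear
in practice, and at ε equal to a group weight they differ.

The DP runs over *token* sequences: segmentation happens before alignment,
and the worked hepatitis-A example (L(A) = 3 after filtration) is a
token-level computation. A character-level mode (`SegmenterConfig.mode =
"char"`) is available, where each atomic unit — one CJK character, or one
whitespace-delimited syllable in the pinyin transcription — is a token.

### Token similarity

`sim` is the maximum of three evidence sources:

* exact (NFC + casefold normalized) surface equality → 1.0;
* membership of both surfaces in a synonym-ontology group → the group
  weight, maximized over shared groups; no transitive closure is applied
  across groups, because synonymy judged per group does not compose safely;
* optionally, the Dice coefficient of the character-bigram sets of the two
  surfaces, to catch small spelling variants; off by default.

With an empty ontology and the fallback off, `sim` is the exact-match
indicator and the semantic DP coincides with the classic LCS for every
ε < 1 — this limit is tested.

### String-level measures

With `LCSL` the LCS length and `L(A) ≤ L(B)` the token counts:

* LCS-ratio: `LCSL / max(L(A), L(B))`
* T-LCS: `2·LCSL / (L(A) + L(B))`
* W-LCS: `(LCSL + 1)·LCSL / (L(A)·LCSL + L(B))`, defined as 0 when
  LCSL = 0 (the formula's limit, continuous with the other measures).

W-LCS ≥ T-LCS ≥ LCS-ratio holds for every admissible triple — the
inequalities reduce to `(LCSL−1)(L(B)−L(A)) ≥ 0` and `L(B) ≥ LCSL` — and
is verified exhaustively up to length 12 in the tests. All three equal 1
iff the sequences fully match at equal length. The published table of
values for L(A) ∈ {1..4} is reproduced exactly at two-decimal round-half-up
rounding; the rows with L(A) ∈ {5, 6} are internally inconsistent with the
printed formulas (e.g. L(A)=5, L(B)=6 lists an LCS-ratio of 0.81 where the
formula gives 5/6 ≈ 0.83) and are carried in the fixtures flagged as
inconsistent, excluded from regression.

Two baselines: word matching (similarity 1 iff the token sequences are
identical, else 0) and a Dice coefficient over boundary-padded adjacent
token pairs. The bigram similarity has no published formula; Dice over
padded token bigrams is the standard n-gram choice, and padding makes
single-token sequences comparable.

## Segmentation

A deterministic forward-maximum-matching segmenter over a user-supplied
lexicon replaces external statistical segmenters: at each position the
longest matching lexicon entry wins (ties on length cannot occur within a
set), and uncovered positions fall back to single atoms. This keeps the
pipeline fully reproducible with no model downloads; reproducing any
particular segmenter's accuracy is a non-goal. A pluggable boundary exists
in practice: any code producing a `TokenSequence` can feed the rest of the
pipeline.

The bundled examples are pinyin transcriptions where whitespace separates
syllables standing for single Chinese characters, so lexicon entries span
whitespace ("BING DU XING GAN YAN" is one five-character word). Atoms are
therefore defined as maximal ASCII-alphanumeric runs or single non-Latin
characters; whitespace delimits atoms but words may span several atoms.

Stop words are removed after segmentation; negation words are exempt and
flagged (`is_negation`), since "without hepatic coma" must not collapse
into "hepatic coma". The default fixture stop list contains only the
connective "BAN" (*with*), with "BU BAN" (*without*) as a negation entry;
no larger published list exists for this task.

## Coding and confidence

A query is scored against every SDL entry (linear scan — tens of thousands
of short sequences is desk-scale) and candidates are ranked by similarity,
with ties broken by larger LCSL (longer matches are more specific), then
shorter standard name (fewer unmatched tokens), then lexicographic code, so
the ranking is total and runs are reproducible. The top candidate's
similarity is the confidence value; confidence above the policy threshold
emits the code automatically, otherwise the record goes to manual review.

Defaults: measure W-LCS, ε = 0.8, synonym-group weight 0.9, confidence
threshold 0.803. The threshold is the published operating point; ε and the
group weight are configuration, not reproduction — no experimental ε was
published — chosen so that listed synonyms (0.9) clear the match threshold
(0.8) while weaker evidence does not. All are configurable.

## Evaluation

Top-1 retrieval framing: a prediction equal to the gold code is a true
positive, a differing prediction a false positive, an abstention (manual
review) a false negative — the relevant record was not retrieved; wrong
predictions are counted once, as false positives. Precision, recall and
F-score follow the usual formulas; when no predictions are made at all,
precision is defined as 0 with a warning so F remains computable. The
threshold sweep ranks each query once and re-applies the policy per
threshold, reporting F-score and coverage (fraction auto-coded); coverage
is non-increasing in the threshold by construction.

## Synthetic benchmark

The real evaluation data (hospital EMR test sets and their gold standard)
are private, so absolute published accuracies are not reproducible. The
generator emulates the *structure* of the task instead: diagnosis names are
2–8-token compositions `modifier* root complication?` over a pinyin-like
ASCII vocabulary; a configurable fraction (default 0.3) of the vocabulary
receives an out-of-vocabulary alias in a weight-0.9 synonym group; queries
are perturbed standard names with known gold codes. Perturbations model
the observed error classes — synonym substitution, dropped/inserted
tokens, single-character typos, abbreviation — and never alter the
disease-root token, so gold labels remain valid without human
adjudication. Generation is a pure function of (parameters, seed).

What passing on this benchmark shows: the mechanics of the pipeline — that
ontology-mediated matches rescue synonym substitutions word matching
cannot, and that the coverage/accuracy trade-off behaves monotonically.
What it does not show: performance on real clinical text, whose typo
distribution, segmentation ambiguity and code granularity are not modeled.
Directional claims (W-LCS ≥ word matching in mean F-score) are asserted as
trends over ≥ 10 seeds at benchmark sizes of 30 codes × 50 queries, never
per run.

## Numerical and degenerate-input choices

* Display rounding is half-up to two decimals (`Decimal`-based); raw
  similarities keep full float precision internally.
* Similarity of two empty sequences is an error (`UndefinedSimilarityError`),
  not 0 or 1; a query that filters to zero tokens raises `EmptyQueryError`.
* Optimal-path traceback prefers diagonal, then up, then left, making
  `matched_pairs` deterministic.
* The brute-force oracle (`brute_force_lcs`) enumerates index subsets and
  greedily embeds each candidate pattern; greedy leftmost embedding is
  exact because the match predicate depends only on the element pair. It
  refuses sequences longer than 12 tokens and exists only for testing.
* Seeds are threaded explicitly everywhere randomness occurs; per-query
  perturbation seeds are derived from the benchmark seed and stored in
  each record.

## Known limitations

* Forward maximum matching can mis-segment genuinely ambiguous Chinese
  strings that statistical segmenters resolve; the lexicon is the user's
  responsibility.
* The synonym ontology is flat: no hyponymy, no similarity decay across
  relation types, no closure. A term pair not sharing a group scores 0
  unless the character fallback fires.
* W-LCS, like the other measures, ignores *which* tokens matched; a missed
  negation token changes the score only by one unit of length (this is why
  negation words are forcibly retained).
* Evaluation is single-code per query; multi-coding documents are out of
  scope.
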