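# Methods

## The identification rule

A clinical note is labeled **positive** for pediatric sleep content iff it
contains at least one match from a tier-1 category of the vocabulary. The
rule has no notion of negation, speculation, or family history: "denies
snoring" is a positive, by design. The rule is intended as a cheap
first-pass filter whose recall matters more than its precision; contextual
validity is left to downstream models or manual review.

## The vocabulary

The packaged bank (`data/dse_vocabulary.json`, version `table2-v1`) holds
37 high-level categories — 30 tier-1 concepts (from "Sleep" and "Insomnia"
through "Bedtime struggles" and "Surgery") and 7 tier-2 concepts
("Wheezing", "Hyperactive", "Dizziness", "Daytime mood", "Tense",
"Inattention", "Nighttime anxiety") whose surfaces appear too often outside
a sleep context to drive identification. Entries are literal phrases (354,
counting repeats) plus six regular expressions (`up to \d+ hours`,
`more than \d+ hours` under Hypersomnia; `less than \d+ hours`,
`sleep \d+ hours` under Sleep duration; `\w+ keeping \w+ up` under Sleep
disturbances; `doing \w+ at night` under Sleep hygiene).

The transcription is deliberately verbatim. Apparent misspellings
("bendryl", "trazadone", "waking up a night") are kept — clinical notes
contain exactly these misspellings, so they may well be intentional
coverage — and the repeated entries inside the Sleep disturbances and
Sleepiness cells are kept as printed. The validator
(`validate_vocabulary`) flags both repeat classes as informational
findings; the matcher de-duplicates at compile time, so repeats are
matching no-ops. One surface, "trouble sleeping", legitimately belongs to
two categories (Sleep quality and Sleep disturbances); a match on it
carries both. The regex sources are stored with the quantifier spacing
normalized (`\d+`, not `\d +`): a space inside the quantifier is a
typesetting artifact that would match nothing of interest. The bank's
entry count (354 literals + 6 regexes, repeats included) is reported by
`vocab_stats` but not enforced against any external figure, since the
count depends on whether repeats and regexes are included.

## Normalization and word boundaries

Matching is defined on a normalized token stream, not on raw text. `normalize`
lowercases and splits on every maximal run of non-alphanumeric characters
(ASCII letters and digits are token characters; everything else — spaces,
punctuation, hyphens, apostrophes straight or curly, non-ASCII letters — is
a boundary), recording for each token its half-open `[start, end)` interval
in the raw string (0-based character coordinates). Consequences:

- "nap" never matches inside "naproxen"; "osa" only as a standalone token;
- "low-energy" and "low energy" are the same token sequence, which
  harmlessly collapses the bank's hyphenated/unhyphenated pair;
- "can’t sleep" (bank spelling) and "can't sleep" (note spelling) tokenize
  identically to `[can, t, sleep]`, while "cant sleep" differs — the bank
  lists "can not sleep" separately to cover dialects.

No sentence splitting, stemming, or spelling correction is performed.
Whether the original system was case-sensitive anywhere is unknown; full
case-folding is adopted here.

## Matching

Literal entries are tokenized and inserted into a token-sequence trie; one
left-to-right scan per note enumerates literal hits under
**longest-leftmost, non-overlapping** resolution — the standard behavior
of trie-based keyword extractors — so the nested "falling asleep" is never
double-counted inside "difficulty falling asleep". Regexes run
independently over the space-joined token string, anchored so a hit cannot
start or end mid-token (`\d+` therefore means one all-digit token, `\w+`
one token), and hit spans are mapped back to raw offsets through the token
offset table. Regex hits are not suppressed by overlapping literal hits:
classification only needs existence, and span-coverage analysis benefits
from completeness. Output is sorted by span; exact duplicates are removed.

`find_matches_bruteforce` re-implements the same contract naively (every
entry scanned at every position, then the identical resolution) and is held
equivalent to the trie path on randomized corpora in the test suite. The
suite also checks structural invariants: every literal match re-normalizes
to its entry's token sequence, and adding tier-1 entries never flips a
positive note negative.

## Evaluation arithmetic

Note-level: 2×2 confusion matrix over positive/negative; precision
= TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean. A metric with an
empty denominator is **undefined** (`None`), never zero — silent zeros
corrupt comparisons. Display rounding is 3 decimals for metrics and 1
decimal for percentages, half away from zero, matching how such tables are
conventionally printed; `recall_delta` reports the recall difference in
percentage points at 1 decimal.

Span-level: gold annotations are standoff spans tagged with one of nine
dimensions — the six Peds B-SATED sleep-health dimensions (behavior,
satisfaction, alertness/daytime sleepiness, timing, efficiency, duration)
plus medication, disorder, and intervention mentions. A span "contains a
keyword" iff at least one **tier-1** match interval lies fully inside it;
full containment is the strictest reading (annotations are word- to
sentence-scale, so a contained keyword is unambiguously credited), and an
any-overlap mode is available behind a flag. The most-present keyword of a
row is the entry surface found inside the largest number of that row's
annotations (annotations, not occurrences), ties broken lexicographically.
A dimension with zero annotations reports an undefined percentage.

`cohen_kappa` is included as the agreement utility for double-annotated
labelings: κ = (p_o − p_e)/(1 − p_e), with expected agreement from the two
marginal distributions; the degenerate p_e = 1 case returns 1.0 for
identical labelings. It is cross-checked against scikit-learn's
implementation in the tests.

## The synthetic corpus

Real pediatric notes cannot be shared, so all end-to-end behavior is
demonstrated on generated well-child-visit-style notes with known ground
truth. A note is a shuffled sequence of short clinic-style sentences drawn
from fixed template banks (no external text resources, so offsets are
stable across platforms):

- **Positive notes** (drawn with probability `prevalence`) receive 1–3
  mention sentences. Each mention either embeds a verbatim tier-1 surface
  in a sentence frame ("Mom reports {kw} most nights.") or, with
  probability `keyword_free_mention_rate`, uses a hand-written keyword-free
  paraphrase of the same dimension ("Lights out around nine, up for school
  at six."). The mention sentence's exact character interval is recorded as
  a gold span.
- **Negative notes** receive filler prose and, at configurable rates, the
  two distractor families that trip keyword rules: negated sleep phrases
  ("denies snoring") and tier-2-only symptom text ("mild wheezing").

Every template is screened against the supplied vocabulary at generation
time: paraphrases and filler must yield zero matches, tier-2 distractors no
tier-1 match, and every pooled surface must actually fire. This makes the
pipeline's boundary behavior exact rather than approximate: with
`keyword_free_mention_rate = 0` and distractors off, recall is 1.0 and
false positives are 0 by construction; with rate *r* and one mention per
note, misses are Binomial(n_pos, r); negation distractors alone drive
precision to 0 at zero prevalence. The keyword-free rate is what makes
span coverage land below 100%, reproducing in kind the ~¾–⅘ coverage a
keyword bank achieves against human annotations.

Defaults mirror the annotated study corpus this tool is aimed at: 300
notes, prevalence 244/300, mention dimensions drawn with the observed
per-dimension tag-count weights, keyword-free rate 0.2, negation distractor
rate 0.5 and tier-2 distractor rate 0.25 among gold negatives. Mention
density per note (1–3) is not empirically grounded — no distributional
facts about it are available — and is documented as an arbitrary default.
A single `random.Random(seed)` stream drives all choices in a fixed order
(per note: label, mentions, distractors, filler, placement), so a config
plus seed reproduces a corpus byte for byte.

## Problem sizes and numerical choices

The arithmetic reproductions (metrics, coverage percentages, recall delta)
are exact computations on printed integer counts and run instantly.
Randomized checks use 1 000 texts for matcher/oracle equivalence and
500-note corpora for end-to-end recall; at these sizes the full suite runs
in well under a minute on one CPU, and the stochastic recall check uses the
exact binomial 99% interval rather than a normal approximation. All seeds
are explicit; the acceptance script derives its generator seeds from the
single `--seed` argument.

## Known limitations

- The rule inherits every documented weakness of keyword matching:
  negation, speculation, non-patient references and template boilerplate
  all produce false positives; paraphrased mentions produce misses.
- The synthetic corpus is a structural testbed, not a linguistic one: it
  validates offsets, determinism, tier logic and the miss/false-positive
  mechanics, but its template prose is far more regular than real
  documentation, so performance numbers on it do not transfer to real
  notes.
- The comparison (SEA) adult vocabulary is not shipped; its published
  confusion matrix is used as printed input, and a user-supplied vocabulary
  file can be evaluated through the same pipeline.
- Tier-2 matches are reported but unused by every headline statistic;
  whether span coverage should ever credit them is resolved here as "no"
  (tier-1 only), the stricter reading.
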