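# pedsleep

Rule-based identification of pediatric sleep-related mentions in clinical
notes.

Pediatric primary-care notes mention sleep in technical terms ("obstructive
sleep apnea"), abbreviations ("osa"), and everyday language ("can't sleep",
"keeping him up"). Deep NLP models can read these, but they are expensive to
run over millions of notes; a keyword vocabulary is not, and works anywhere.
`pedsleep` implements that low-resource first pass: it ships a two-tier
pediatric sleep keyword bank (the DSE bank — 37 high-level categories, 30 of
which are tier 1, as literal phrases plus six token-level regular
expressions), compiles it into a whole-word multi-pattern matcher, labels a
note **positive** when it contains at least one tier-1 match, and scores
predictions at the note level (precision / recall / F1 from a 2×2 confusion
matrix) and at the span level (the fraction of gold-annotated mention spans,
tagged with one of nine sleep-health dimensions, that contain a tier-1
keyword). Tier-2 categories (e.g. "wheezing", "irritable") are matched and
reported but deliberately excluded from the note rule because they are
ambiguous outside a sleep context.

Because real clinical notes cannot be shared, the package includes a seeded
synthetic well-child-visit note generator with gold labels and gold
standoff spans, including the failure modes a keyword rule is known to have:
negated mentions ("denies snoring") that become false positives, and
keyword-free paraphrases that become misses.

## Worked example

```python
from pedsleep import load_vocabulary, compile_matcher, find_matches, classify_note

vocab = load_vocabulary("dse")
matcher = compile_matcher(vocab)

text = "Mom reports he snores loudly and sleeps less than 6 hours on school nights."
for m in find_matches(matcher, text):
    print(f"[{m.char_start:2d},{m.char_end:2d}) {m.matched_text!r:22s} {m.kind:7s} {m.categories}")

c = classify_note(matcher, "note-1", text)
print(c.label, len(c.tier1_matches), len(c.tier2_matches))
```

prints

```
[15,21) 'snores'               literal (('Snoring', 1),)
[33,39) 'sleeps'               literal (('Sleep', 1),)
[40,57) 'less than 6 hours'    regex   (('Sleep duration', 1),)
positive 3 0
```

Three tier-1 hits: two literal keywords (matched on whole words — "snores"
would never fire inside "snoresome") and one regex, `less than \d+ hours`,
matched on the normalized token stream and mapped back to raw character
offsets. Any tier-1 hit makes the note positive.

The same pipeline from the shell, on a 300-note synthetic corpus:

```bash
pedsleep generate --n 300 --seed 11 --out demo/
pedsleep evaluate --notes demo/notes.jsonl --gold-labels demo/gold_labels.jsonl \
                  --annotations demo/gold_annotations.jsonl
```

```
cell    count
tp      221
fp      25
fn      21
tn      33
precision       0.898
recall  0.913
f1      0.906
dimension       total   containing      percentage      most_present
...
ALL     470     368     78.3    bedtime routine (19)
```

The generator's default confounder rates plant negated sleep phrases in
some gold-negative notes (the 25 false positives) and phrase roughly one
mention in five without any bank keyword (the misses and the ~78% span
coverage): the characteristic behavior of a keyword rule, reproduced with
known ground truth.

Other commands: `pedsleep vocab-stats` (category/entry counts),
`pedsleep tag` (all matches per note as JSONL), `pedsleep classify`
(labels only). All note-shaped data is JSONL; `--vocab` accepts the builtin
`dse` or a user vocabulary file in the documented JSON schema
(`{"version", "categories": [{"name", "tier", "literals", "regexes"}]}`).

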