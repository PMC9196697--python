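# cohortcraft

Turn free-text clinical-trial eligibility criteria into structured, editable
representations and executable cohort queries.

The pipeline:

1. **Parse** — split a criteria block into inclusion/exclusion sentences,
   recognize entities (lexicon + patterns), detect negation-cue scopes,
   and normalize temporal expressions (index-date-relative day windows)
   and value expressions (comparison-operator/value terms) into a
   versioned JSON document.
2. **Edit** — a programmatic human-in-the-loop API: add/update/delete
   concepts, delete all concepts in a criterion, and (de)select criteria,
   with every action logged as an append-only event.  Replaying the log on
   the machine baseline reproduces the edited document exactly.  Concept
   lookup runs against a local catalog with exact and fuzzy search.
3. **Query** — compile the representation into a single SQL statement over
   an OMOP-CDM-v5-shaped store (SQLite for embedded execution; PostgreSQL
   text emitted for parity), execute it, and report cohort demographics
   (patient ID, age at index, gender, race).

A synthetic-fixtures module generates seeded criteria corpora with gold
labels and OMOP-lite databases with planted, exactly-known cohorts, so the
whole pipeline is testable offline.

## CLI

```bash
# parse criteria text into the JSON representation
cohortcraft parse criteria.txt --lexicon lexicon.csv --trial-id NCT1 -o rep.json

# apply a batch of edits (JSON-lines; one action per line)
cohortcraft edit rep.json edits.jsonl

# compile + execute the cohort query; write person_id,age,gender,race CSV
cohortcraft query rep.json omop.sqlite --dialect sqlite -o cohort.csv

# generate the synthetic fixtures (gold corpus + planted database)
cohortcraft gen-fixtures --n 100 --seed 0 --out-dir fixtures/

# entity counts and modification summary
cohortcraft report rep.json
```

Exit codes: `0` success, `2` unreadable/invalid input, `3` empty query
(no queryable, selected annotations).

Lexicon CSV columns: `surface_form,category,concept_id,concept_name,domain,
vocabulary,standard`.  Concept catalog CSV adds a pipe-delimited `synonyms`
column.  The JSON document layout is described in
[docs/criteria_schema.md](docs/criteria_schema.md).

## Normalization conventions

- Temporal windows are `(start_days, start_offset, end_days, end_offset)`
  with offset `-1` = before and `+1` = after the index start date; the
  open-bound sentinel is 9999 days.  Units unify to days: hours round up,
  week = 7, month = 30, year = 365.
- `"at least N days before X"` → window (9999 before, N before);
  `"within N days prior to X"` → (N before, 0 before);
  `"A to B weeks post X"` → (7A after, 7B after).
- Values: `"up to"`→`<=`, `"or higher"`→`>=`, …(editable dictionary at
  `src/cohortcraft/resources/operators.csv`); a `%` divides the adjacent
  number(s) by 100; `N+` means `>= N`; ranges become `>= a AND <= b`;
  Roman numerals I–X are numbers; numbers inside unit denominators
  (`3 g/24-hours`) are never values.
- Negation: rule-based rightward scope from each cue to the next clause
  boundary, aggregated per entity by majority vote over word labels
  (ties count as negated).  A terminal period is added to unterminated
  sentences before scope detection.

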