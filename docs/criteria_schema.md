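# Criteria-representation JSON schema (version 1)

One document per trial, UTF-8, produced by `cohortcraft.model.write_json`
and validated on read.  All character offsets are 0-based, half-open
offsets into the owning criterion's `text`.

```jsonc
{
  "schema_version": 1,
  "trial_id": "NCT04249869",
  "criteria": [
    {
      "trial_id": "NCT04249869",
      "section": "inclusion",        // "inclusion" | "exclusion"
      "index": 0,                    // >= 0, unique per (trial, section)
      "text": "Hemoglobin A1c > 7.5",
      "selected": true               // deselected => excluded from queries
    }
  ],
  // keyed by "<section>:<index>"
  "annotations": {
    "inclusion:0": [
      {
        "annotation_id": 0,          // unique within the document
        "span": [0, 14],             // surface == text[span[0]:span[1]]
        "surface": "Hemoglobin A1c",
        "category": "Measurement",   // Condition | Drug | Measurement |
                                     // Procedure | Observation |
                                     // Person_attribute | Value |
                                     // Temporal | Negation_cue
        "concepts": [                // empty for Value/Temporal/Negation_cue
          {
            "concept_id": 3004410,   // > 0
            "concept_name": "Hemoglobin A1c measurement",
            "domain": "Measurement",
            "vocabulary": "LOINC",
            "standard": true
          }
        ],
        "negated": false,
        "provenance": "machine",     // "machine" | "human"
        "value_constraint": null,    // set on normalized Value entities
        "temporal_constraint": null  // set on normalized Temporal entities
      }
    ]
  },
  "edit_log": [
    {
      "action": "add_concept",       // add_concept | update_concept |
                                     // delete_concept |
                                     // delete_all_in_criterion |
                                     // select_criteria
      "criterion_key": "inclusion:0",
      "payload": { },                // action-specific, replayable
      "timestamp": 0,                // strictly increasing sequence number
      "actor": "human"
    }
  ],
  "warnings": [],
  "next_annotation_id": 1
}
```

Constraint objects:

```jsonc
// temporal: event starts between start_offset*start_days and
// end_offset*end_days days from the index start date (-1 before, +1 after);
// 9999 is the open-bound sentinel.  Signed start <= signed end.
{"start_days": 9999, "start_offset": -1, "end_days": 5, "end_offset": -1}

// value: operator/value terms joined by a logical relation; values are
// exact decimals serialized as strings
{"terms": [{"operator": ">=", "value": "0.344"},
           {"operator": "<=", "value": "0.446"}],
 "logic": "and",                     // "and" | "or" | "single"
 "unit": ""}
```

Validation guarantees: `read_json(write_json(rep)) == rep` field for field;
every annotation key names an existing criterion; every surface equals its
text slice; malformed documents raise a validation error naming the
offending path.
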