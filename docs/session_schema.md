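# Typing-session record schema

Typing sessions are exchanged as JSON Lines (`.jsonl`): one JSON object per
line, one object per keyboard session.

```json
{"session_id": "abc-001", "subject_id": "u017",
 "press":   [1600000000000, 1600000000180, 1600000000350],
 "release": [1600000000090, 1600000000265, 1600000000440]}
```

Fields:

| field        | type        | meaning                                             |
|--------------|-------------|-----------------------------------------------------|
| `session_id` | string      | opaque unique id of the keyboard session            |
| `subject_id` | string      | opaque pseudonymous subject id                      |
| `press`      | int array   | key-press timestamps, milliseconds since epoch      |
| `release`    | int array   | key-release timestamps, paired index-wise with `press` |

Validity rules (violations reject the record, with a logged warning):

* `len(press) == len(release) >= 1`;
* `press` sorted ascending;
* `release[i] >= press[i]` for every event.

No character content is ever represented — the schema carries timing only,
mirroring the privacy-by-design collection the pipeline is built for.
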