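# rtdx

A referent-tracking knowledge-base engine for diagnostic assertions.

`rtdx` stores temporally indexed assertions about *particulars* (`IUI-n`),
*universals* (`UUI-n`) and temporal regions (`tn`), evaluates the aboutness
of diagnostic contents at two levels — reference (does each mentioned entity
exist?) and compound expression (does the asserted configuration of
organism, disease and disease type exist as stated?) — and classifies each
assertion by content *and provenance* into:

- **correct diagnosis** — produced by a diagnostic process (clinical picture
  plus an aggregate of disease-type/phenotype-type representations as
  inputs; the agent may be human or a machine), compound aboutness holds;
- **misdiagnosis** — diagnostic pedigree, compound aboutness fails;
  annotated with six single-fault failure modes (wrong-but-existing type,
  nonexistent type, nonexistent disease, nonexistent organism, wrong
  bearer, spacetime misplacement) and whether the failure first appears at
  the reference or compound level;
- **lucky guess** — coincidentally correct, no diagnostic pedigree;
- **hearsay/copy** — a representation produced by copying, which concretizes
  the original information content entity (ICE) rather than creating a new
  one;
- **justified conclusion** — a layperson's correct belief derived from a
  prior diagnosis;
- **non-ICE** — fails in aboutness on every referent, hence about nothing.

Temporal entailment is three-valued (`holds` / `fails` / `indeterminate`)
over a closed vocabulary of seven interval relations, decided by
shortest-path closure of a difference-constraint network over interval
endpoints.

## Layout

| module | contents |
| --- | --- |
| `rtdx.core_model` | domain types, record validation, configuration builder |
| `rtdx.kb_store` | `KnowledgeBase`: assertions, queries, temporal entailment, consistency checks |
| `rtdx.aboutness` | two-level aboutness evaluation; derivation of `is_about` / `is_misrepresentation_of` |
| `rtdx.provenance` | ICE identity: copying vs authoring, conformance |
| `rtdx.dx_classifier` | diagnostic-process test, failure modes, category cascade, precision warning |
| `rtdx.scenarios` | six worked fixture KBs, single-fault perturbation, seeded synthetic KBs |
| `rtdx.io_cli` | versioned RT tuple JSON format, TSV view, OWL export (Turtle/functional), CLI |

## CLI

```sh
rtdx scenario 3 --out s3.json      # emit a fixture KB
rtdx validate s3.json              # closure, clash and temporal checks
rtdx classify s3.json              # -> {"category": "misdiagnosis", ...}
rtdx perturb s3.json --mode SPACETIME_MISPLACEMENT --seed 7 --out s3-mut.json
rtdx export s3.json --dialect turtle
```

`classify` prints category, failure modes, where aboutness fails first, and
the rule-by-rule rationale trail. All commands exit non-zero with a JSON
error report on bad input.

## API sketch

```python
from rtdx import build_scenario, classify_target, infer_aboutness_relations

kb, target = build_scenario(3)
result = classify_target(kb, target)
result.category.value        # 'misdiagnosis'
result.failure_modes         # {NONINST_TYPE_EXISTS}
result.fails_first           # 'compound'

rep = kb.representations["IUI-46"]
infer_aboutness_relations(rep, kb)   # 3 is_about + 1 is_misrepresentation_of
```

## Notes on the OWL export

Aboutness toward particulars is emitted as ordinary object-property
assertions; aboutness toward universals is demoted to annotation triples
(types cannot sit in an OWL object property's range); misrepresentation is
a distinct property. The export never emits universally quantified
("only") aboutness restrictions. `rtdx.io_cli.parse_turtle` is a minimal
Turtle reader used to conformance-check the emitted documents offline.
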