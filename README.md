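# drbank

Toolkit for PDTB-style stand-off discourse relation banks over biomedical
full-text articles: the pipe-delimited annotation format, the two-tier
sense taxonomy (16 types / 31 leaf categories) with its generalization
onto the four top-level classes (Comparison, Contingency, Temporal,
Expansion), inter-annotator agreement measures, descriptive corpus
statistics, connective-string-only sense classification experiments, and
a synthetic-corpus generator with known ground truth.

## Layout

| Module | Purpose |
| --- | --- |
| `drbank.model` | Spans, sense labels, taxonomy, class mapping, relation records, validation |
| `drbank.standoff` | Pipe-delimited stand-off reader/writer, span parsing, text extraction |
| `drbank.agreement` | Connective-overlap matching, exact/partial argument agreement, Cohen's kappa |
| `drbank.corpus_stats` | Relation-type / sense / ambiguity / section-wise distribution tables |
| `drbank.sense_classifier` | Per-connective majority-rule classifier, k-fold CV, learning curves, cross-domain eval |
| `drbank.synthesis` | Seeded corpus generator, noisy second-annotator derivation, table fixtures |
| `drbank.tables` | Published summary-table constants backing the fixtures |

## Annotation format

Annotation files are flat text, one relation per line, fields separated
by `|` (27 columns by default; configurable via `FormatDialect`). The
meaningful fields are: 0 relation type, 1 connective span offsets,
7 inserted implicit connective, 8/9 first/second sense, 14 Arg1 spans,
20 Arg2 spans. Span fields use `start..end` character offsets
(half-open by default; an inclusive-end dialect flag exists), with
discontinuous spans semicolon-separated. Source documents are plain
UTF-8 text; annotations pair with sources by file stem
(`doc.txt` / `doc.ann`).

## CLI

```sh
drbank validate  SRC_DIR ANN_DIR                 # lint a corpus
drbank convert   SRC_DIR ANN_DIR OUT --to-n-fields 48
drbank stats     SRC_DIR ANN_DIR --table types|senses|ambiguity|imrad
drbank agreement SRC_DIR ANN_A ANN_B             # two-annotator report
drbank classify  SRC_DIR ANN_DIR --granularity class --slot first --folds 10
drbank simulate  --config cfg.yaml --out DIR [--perturb noise.yaml]
drbank simulate  --fixture table4 --out DIR
```

A generator config is YAML mirroring `SynthConfig`, e.g.

```yaml
n_relations: {Explicit: 500, Implicit: 200}
connectives:
  since: {Cause.Reason: 0.6, Temporal.Succession: 0.4}
  but:   {Contrast: 1.0}
multi_sense_rate: 0.074
seed: 7
```

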