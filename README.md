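# paduavte

Automated Padua VTE (venous thromboembolism) risk assessment from EMR
text, built as two cooperating branches:

* **Branch A** — a disease-category classifier over (diagnosis,
  symptoms) units. Texts are vectorized to 20×768 / 50×768 embedding
  matrices, encoded by two stacked bidirectional recurrent layers into
  768-wide features, fused with a 6-wide TF-IWF **symptom weight
  vector**, and classified with a focal-loss softmax head into five
  Padua disease items + "Others". Training uses a stratified 7:3
  split, 10% uncertainty-marker negative amplification, a 100-epoch
  cap and patience-10 early stopping on validation F1.
* **Branch B** — lexicon-intervened segmentation of narrative
  sections, greedy longest-match term matching, clause-scoped negation
  filtering, a ≤30-day time window for recent trauma/surgery, and
  numeric rules for age ≥ 70, BMI ≥ 30 and thrombophilia labs.

The 11 item flags are scored by the standard Padua weights (total 20
points) and stratified at the default cutoff of 3. A seeded synthetic
generator produces corpora, lexicons, training units and full EMRs
with exact gold flags, so the whole pipeline runs offline with no
model downloads and no private data.

## Layout

| Module | Purpose |
| --- | --- |
| `paduavte.scale` | Padua items, weights, total score, risk levels |
| `paduavte.swm` | TF-IWF statistics and symptom-weight-vector construction |
| `paduavte.tokenize` | lexicon-driven segmentation, clause/sentence splitting, time parsing |
| `paduavte.extractor` | Branch B matching, negation, time-window and numeric rules |
| `paduavte.vectorize` | deterministic hashed embedder behind a pluggable vectorizer contract |
| `paduavte.encoder` | stacked bidirectional recurrent encoder (numpy) |
| `paduavte.model` | Branch A training, prediction, persistence |
| `paduavte.metrics` | AUC, F1, HD, OE, RL, Cov, sensitivity/specificity/precision |
| `paduavte.synth` | seeded synthetic fixtures with known ground truth |
| `paduavte.assess` | end-to-end assessment and batch evaluation |
| `paduavte.io` / `paduavte.cli` | JSON Lines / lexicon / config I/O and the CLI |

The recurrent encoder parameters are deterministic functions of the
seed and stay fixed during training; the focal-loss classification
head on top is what training fits (no deep-learning framework is
required — only numpy). A pretrained transformer embedder can be
plugged in by implementing the `Vectorizer` contract.

## CLI

```sh
# generate a synthetic fixture bundle (lexicons, corpora, units, EMRs)
paduavte simulate --seed 1 --n-records 200 --n-units 600 --out-dir scratch/fixtures

# precompute the symptom weight statistics
paduavte build-swm --corpora scratch/fixtures/corpora.tsv --out scratch/swm.json

# train the disease-category classifier
paduavte train --units scratch/fixtures/units.jsonl \
    --corpora scratch/fixtures/corpora.tsv --model-dir scratch/model --seed 1

# assess and evaluate an EMR batch
paduavte assess --emr scratch/fixtures/emr.jsonl --lexicon-dir scratch/fixtures \
    --model-dir scratch/model --out scratch/assessments.jsonl
paduavte evaluate --emr scratch/fixtures/emr.jsonl --lexicon-dir scratch/fixtures \
    --model-dir scratch/model --out scratch/metrics.json
```

EMR batches are JSON Lines (one record per line, ISO-8601 dates; see
`src/paduavte/schemas/`), lexicons are UTF-8 term-per-line files, and
category corpora are `term<TAB>category<TAB>count` TSV.

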