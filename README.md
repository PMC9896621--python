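# posevote

Docking-augmented machine-learning triage for ligand bioactivity
classification. Multiple docked poses per compound are turned into binary
ligand–receptor contact fingerprints (one bit per binding-site atom, 2.5 Å
cutoff) plus scoring-function values; poses are filtered by top-20% consensus
votes and heavy-atom RMSD deduplication; six learner families are scanned with
leave-20%-out cross-validation; descriptors are refined by a two-phase
genetic algorithm with Cohen's kappa as fitness and a SHAP class-consistency
filter; the surviving descriptors drive template-pose selection, rule-based
pharmacophore extraction, and an active-pose-ratio threshold for virtual-
screening triage.

## Modules

| module | role |
| --- | --- |
| `posevote.io_model` | domain types + PDB/SDF/CSV readers and writers |
| `posevote.labeling_split` | IC50 → activity classes; every-fifth train/test split |
| `posevote.contacts` | binary contact fingerprints over the site-atom axis |
| `posevote.consensus_dedup` | top-20% consensus votes; RMSD pose dedup |
| `posevote.ml_engine` | feature assembly, learner scan, accuracy/kappa/ROC |
| `posevote.gfa_select` | two-phase genetic-algorithm descriptor selection |
| `posevote.shap_consistency` | Shapley probability contributions + consistency filter |
| `posevote.pharmacophore` | rule-based pharmacophore extraction and mapping |
| `posevote.screening` | active-pose-ratio threshold and hit triage |
| `posevote.synthetic_fixtures` | synthetic inputs with a planted contact→activity signal |

Shapley attribution is computed in-package (interventional values against a
k-means-summarised background; exact coalition enumeration for ≤12 features,
antithetic permutation sampling beyond) — local accuracy (contributions sum to
prediction − baseline) holds exactly. The `xgb` learner key is backed by
scikit-learn gradient-boosted trees.

## CLI

```bash
# synthesise a project with a planted signal, then run the stages
posevote simulate --seed 17 --out proj/
posevote contacts  --project proj/
posevote consensus --project proj/ --top 0.2
posevote dedup     --project proj/ --rmsd 2.0 --min-votes 1
posevote train     --project proj/ --learners rf,xgb,nb,knn,pnn,mlp --seed 17
posevote gfa       --project proj/ --learner rf --preset desk --seed 17
posevote shap      --project proj/ --learner rf --seed 17
posevote pharmacophore --project proj/ --pose C0001#1
posevote triage    --model xgb --min-poses 2

# external data
posevote ingest --receptor X.pdb --site site.yaml --poses P.sdf \
    --scores S.csv --directions directions.yaml --activities A.csv --out proj/
posevote label --activities A.csv --active-max 5000 --inactive-min 20000
posevote split --activities A.csv --seed 17

# one-shot end-to-end recovery report on default fixtures
posevote recover --seed 17 --preset desk
```

`--preset desk` is a scaled-down GA schedule for single-CPU runs; `--preset
paper` keeps the published population sizes and generation counts.

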