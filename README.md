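# glycosite

Sequence-based prediction of protein glycosylation sites (N-, O- and C-linked)
in eukaryotic proteins with support-vector machines, plus the supporting
machinery a site-prediction study needs: pattern construction from annotated
sequences, redundancy reduction, feature encoding, model selection by
cross-validation, sequon scanning, site statistics, and a seeded synthetic
benchmark generator.

## The problem

Glycosylation is a common covalent modification of proteins. N-linked glycans
attach to asparagine, O-linked glycans to serine/threonine, and C-linked
mannose to tryptophan. The canonical N-sequon Asn-X-Ser/Thr (X ≠ Pro) is
necessary but far from sufficient — most sequons are never glycosylated — so
the prediction task is: given a candidate residue and its sequence
neighbourhood, decide whether it is a true site.

The model here follows the classic window approach. Each candidate residue is
the centre of a fixed-length window (default 21 residues, termini padded with
the dummy residue `X`), the window is encoded as a numeric feature vector, and
an RBF-kernel SVM is trained on windows labelled by experimental annotation.
See [docs/methods.md](docs/methods.md) for the full methodology.

## Worked example

The bundled `examples/smoke.yaml` defines a small synthetic study: 40
proteins, ~20% of eligible Asn residues glycosylated, with an enriched
sequence context around true sites (Pro at −3, Gly at −1, Ala at +3, each at
background + 0.5 frequency).

```bash
glycosite simulate --config examples/smoke.yaml --out smoke/
# wrote smoke/proteins.fasta, smoke/annotations.tsv, smoke/manifest.json

glycosite build-dataset --fasta smoke/proteins.fasta \
    --annotations smoke/annotations.tsv --type N \
    --prune-cutoff 90 --seed 7 --out smoke/
# 181 patterns (49 positive); train 145, independent 36

glycosite encode --patterns smoke/train.tsv --features BPP \
    --out smoke/train_features.tsv
# wrote 145 x 441 features (BPP21)

glycosite gridsearch --features smoke/train_features.tsv --folds 5 --seed 7 \
    --gammas 0.01,0.001 --costs 1,2,3 --cost-factors 1,2 \
    --model smoke/model.joblib --table smoke/cv.tsv
# best config: gamma=0.01 C=2.0 j=2.0; model -> smoke/model.joblib

glycosite evaluate --patterns smoke/train.tsv --gamma 0.01 --cost 2 \
    --cost-factor 2 --folds 5 --seed 7 --out smoke/cv_report.tsv
# mean Acc 94.48% MCC 0.859 AUC 0.988 -> smoke/cv_report.tsv

glycosite encode --patterns smoke/independent.tsv --features BPP \
    --out smoke/ind_features.tsv
glycosite predict --model smoke/model.joblib --features smoke/ind_features.tsv \
    --threshold 0 --out smoke/predictions.tsv
# 7 of 36 predicted positive at t=0.0
```

Scanning arbitrary sequences for sequons needs no model:

```bash
glycosite scan --fasta query.fasta --types N,C --out matches.tsv
# q1: 3 N residues, 4 sequon matches
```

yields one row per match, e.g. `q1  13  N-X-S/T  canonical  NAT`.

Other subcommands: `prune`, `cluster`, `split`, `balance` (dataset curation),
`train` (fixed hyperparameters), `stats` (positional residue frequencies and
the site-position histogram). All accept `--seed` where randomness is
involved; identical seeds give byte-identical outputs.

## Library use

```python
from glycosite import (
    GlycoType, SyntheticConfig, generate, build_patterns,
    make_encoder, encode_dataset, grid_search, cross_validate, scan_n,
)

dataset = generate(SyntheticConfig(n_proteins=40, seed=7))
```

Every CLI stage is a thin wrapper over these functions; intermediate
artifacts (pattern TSV, feature TSV, joblib model) are plain files so each
stage is independently scriptable and testable.

## Layout

- `src/glycosite/` — the package: `core` (records, FASTA/annotation I/O),
  `patterns`, `redundancy`, `features`, `model`, `evaluation`, `scanner`,
  `stats`, `simulate`, `cli`.
- `tests/` — unit, property-based (hypothesis) and acceptance tests;
  `tests/test_acceptance.py` certifies the release criteria.
- `scripts/acceptance.py` — standalone reproduction of the headline numbers.
- `docs/methods.md` — scientific methodology and design rationale.
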