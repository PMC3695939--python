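# Methods

This document records the scientific methodology implemented by `glycosite`:
what is computed, with which parameters, and why each design choice was made.

## 1. Problem formulation

Given a protein sequence and a glycosylation type, every residue of the
matching anchor type is a candidate site: asparagine for N-linked,
serine/threonine for O-linked, tryptophan for C-linked glycosylation. The
predictor decides, per candidate, whether the residue is glycosylated, using
only its local sequence neighbourhood (optionally augmented with evolutionary
and structural profiles).

## 2. Patterns (windows)

Each candidate residue becomes a **pattern**: a window of fixed odd length
*L* (default 21) centred on the candidate. Termini are padded with (L−1)/2
copies of the dummy residue `X`, so every candidate — including those near a
terminus — yields a full-length window. The working alphabet is therefore 21
symbols: the 20 standard amino acids plus `X` (listed last; amino acids in
alphabetical one-letter order). Nonstandard residue codes (B, J, O, U, Z, \*)
are mapped to `X` on input with a warning.

A pattern is **positive** if its centre is experimentally annotated as
glycosylated, otherwise negative. Negatives are real candidate residues from
the same annotated proteins — including residues inside valid sequons — which
makes the task realistic rather than trivially separable.

L = 21 is the default because site-determining context in glycosylation is
local (roughly ±10 residues) and because it keeps the binary encoding at a
size (441) where hundreds-to-thousands of patterns train in seconds. It is a
parameter (`PatternConfig.window_length`), not a constant.

## 3. Redundancy reduction

Homology between training and evaluation instances inflates performance
estimates, so two levels of redundancy reduction are provided:

- **Protein level** (`cluster_proteins`): greedy incremental clustering.
  Sequences are sorted longest-first; each joins the first kept
  representative whose global-alignment identity exceeds the cutoff
  (typically 40%), else founds a new cluster. Alignment uses BLOSUM62 with
  gap open 10 / extend 1; identity is aligned identical residues divided by
  the shorter sequence's length. This is the classic greedy clustering
  scheme with exhaustive alignments instead of k-mer prefilters — exact and
  fast enough at study scale.
- **Pattern level** (`prune_patterns`): windows are pre-aligned by their
  centre, so identity is plain positionwise percent identity (`X` matches
  only `X`). Greedy filtering keeps a pattern iff its identity to every
  already-kept pattern is ≤ the cutoff; exact duplicate windows are always
  removed, so the 100% rung of the cutoff ladder (100…40%) deduplicates.
  Positives are processed first so that a negative nearly identical to a
  kept positive is the one removed.

A dataset with no two windows above 60% identity is the most stringent tier
and gives the most honest cross-validation numbers.

## 4. Feature encodings

All encoders produce flat vectors with a recorded schema string (e.g.
`BPP21`, `BPP21+CPP`); models refuse feature sets whose schema differs from
the one they were trained on.

- **BPP** (binary profile): each window position one-hot over the 21-symbol
  alphabet → 21·L dimensions (441 at L = 21). `A` maps to the first unit
  vector, `X` to the last.
- **CPP** (composition): 20-dimensional amino-acid fraction of the window;
  pads are excluded from the denominator, so CPP always sums to 1.
- **PPP** (evolutionary profile): per-position 20-dim profile rows squashed
  through the logistic 1/(1+e^−x) → 20·L dimensions; pad positions
  contribute zero rows. Profiles come from a `ProfileProvider` — a bundled
  PSI-BLAST ASCII PSSM parser, or the offline `SubstitutionMatrixProfileProvider`
  (BLOSUM62 rows) when no alignment profile is available.
- **SS** (secondary structure): per-position coil/helix/strand probabilities
  (3·L), from a PSIPRED `.ss2` parser or an offline Chou–Fasman-propensity
  provider.
- **ASA** (accessibility): per-position relative accessible surface area
  scaled to [0, 1] (L dims); the offline provider derives a proxy from the
  Kyte–Doolittle scale.

Encodings combine by concatenation (`make_encoder(["BPP", "CPP"])`).

## 5. Classifier and model selection

The classifier is a support-vector machine with RBF kernel
K(u, v) = exp(−γ‖u−v‖²), with cost C and a class-weight factor j that
multiplies the penalty on positive-class errors — the standard remedy when
negatives dominate. Decision threshold t (default 0) is applied to the SVM
decision value; raising t trades sensitivity for specificity.

**Grid search** (`grid_search`) evaluates the full default grid
γ ∈ {1, 0.1, 0.01, 0.001, 10⁻⁴, 10⁻⁵} × C ∈ {1…10} × j ∈ {1…4}
(240 points) by stratified 5-fold cross-validation, selecting the point with
the best mean MCC at t = 0; ties break by higher mean accuracy, then smaller
C, then smaller γ (preferring the smoother model). The full per-point table
is returned so alternative selection rules can be re-derived from it.

Implementation note: all grid points share the folds, so the squared
Euclidean distance matrix is computed once and each (γ, fold) kernel is a
single elementwise exponential passed to a precomputed-kernel SVM. This is
numerically identical to refitting an RBF SVM per grid point (verified by a
dedicated test at 10⁻⁹ tolerance) and makes the full grid run in about a
minute on ~2200 patterns with one CPU.

## 6. Evaluation

Threshold-dependent metrics are computed from the confusion matrix:
sensitivity, specificity and accuracy as percentages, and the Matthews
correlation coefficient (MCC), with the convention MCC = 0 when a
denominator factor vanishes. Threshold-independent performance is the area
under the ROC curve (trapezoidal; equal scores contribute 0.5 concordance).
Cross-validation is stratified k-fold (default k = 5) — stratification keeps
every fold's class ratio intact on imbalanced data — reporting per-fold
metrics plus across-fold mean ± sample (n−1) standard deviation. Each
instance is tested exactly once.

A 4:1 stratified train/held-out split (`split_patterns`) and seeded
balanced subsampling of negatives (`balance`) support the usual
balanced-training / realistic-testing protocol.

## 7. Sequon scanner

Independent of any model, `scan_n` / `scan_c` / `scan_exceptional` locate
motifs exactly:

- canonical N-sequon `N-X-S/T` with X ≠ P (mode `canonical`), or
  unrestricted `N-X-S/T` (mode `nxst_all`);
- C-sequons `W-X-X-W`, `W-X-X-C`, `W-X-X-F`;
- an extensible library of exceptional motifs (defaults `N-P-S/T`, `N-X-C`)
  defined in a mini-format (`N [^P] [ST]`), loadable from a text file.

Overlapping matches are all reported; `annotate` renders bracketed match
spans, merging overlaps leftmost-first.

## 8. Site statistics

`positional_frequency` builds the per-offset residue frequency matrix of a
pattern set (pads are first-class symbols, so every column sums to 1) — the
numeric counterpart of a sequence logo. `spread_histogram` bins annotated
site positions by relative location along the protein (upper-inclusive bins),
showing where in the chain sites concentrate.

## 9. Synthetic benchmark generator

Because curated glycosylation corpora are built from external databases and
alignment tools, the package ships its own ground-truth generator
(`simulate.generate`) for calibration and acceptance testing:

- sequences drawn i.i.d. from a background composition (uniform 1/20 by
  default; a SWISS-PROT-like preset is bundled);
- each eligible anchor is promoted to a true site with probability
  `positive_rate`, in seeded random order, with edit spans kept disjoint;
- each planted site receives a positional signal: at each configured offset
  the residue is resampled so its marginal frequency is exactly
  background + excess (feasibility is validated up front);
- N-sites are always embedded in a valid canonical sequon, C-sites in
  `W-X-X-[W/C/F]`; the sequon-enforcement positions are part of the
  reserved span, so neighbouring sites never clobber each other's signal;
- a JSON manifest records every planted site and every accidental candidate,
  enabling exact scanner expectations;
- output is byte-identical for identical configs and seeds.

The generator's defaults are the study conditions used throughout the tests
and the acceptance script; they were chosen a priori (e.g. +0.5 excess on
three offsets is a strong but not degenerate signal) and are not tuned to
outcomes. Calibration is itself tested: with zero excess, signal-offset
frequencies match background within three standard errors.

Scope limits: the generator does not model domain architecture, realistic
evolutionary profiles, or inter-site correlation beyond span disjointness. A
small cross-talk effect is expected and accepted: a planted site's signal
edits can fall just outside a neighbouring site's window-edge offsets,
slightly enriching signal residues at distances beyond the reserved span.

## 10. Benchmark problem sizes

The acceptance benchmark uses 125 proteins (~2300 patterns), a 200-positive /
2000-negative subsample (1:10 imbalance, mimicking realistic candidate
ratios), the full 240-point grid and 5-fold CV. These sizes are this
package's choice: large enough that CV AUC estimates are stable to ±0.01 and
a planted signal of +0.5 excess is unmistakable (best AUC ≈ 0.99 vs ≈ 0.50
on shuffled labels), small enough to run in about a minute on one CPU.

## 11. Numerical conventions

- MCC denominator of zero → MCC = 0 (not NaN).
- ROC AUC by trapezoidal integration over the full ROC curve; tied scores
  contribute half-concordance.
- Percent metrics are reported in [0, 100]; MCC and AUC as fractions.
- Identity cutoffs are strict: a pattern is removed only if identity
  *exceeds* the cutoff (with the exact-duplicate exception at any cutoff);
  a protein joins a cluster only if identity *exceeds* the cutoff.
- Train-set size per class in splits is round(fraction · n).
- All stochastic steps (generation, subsampling, splits, folds) take
  explicit integer seeds; no global RNG state is used.

## 12. Limitations

- Predictions use sequence-local context only; no glycan-type-specific
  enzymology, subcellular localisation, or structure beyond the optional
  SS/ASA features.
- The offline profile/structure providers (substitution-matrix rows,
  Chou–Fasman propensities, hydropathy-derived ASA) are deliberately crude
  stand-ins; for real studies, supply PSI-BLAST PSSMs and PSIPRED/ASA
  predictions through the file-based providers.
- Greedy clustering and pruning are order-dependent heuristics (by design,
  for reproducibility they use fixed deterministic orderings).
- Performance on real curated data depends on annotation quality and
  redundancy handling; the synthetic benchmark certifies the machinery, not
  biological generalisation.
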