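# Methods

## Model and assumptions

`protint` treats "is a partner of protein T" as a binary classification
problem over single-protein sequence features. The underlying assumptions
are:

1. the partners of one target protein share detectable sequence-level
   regularities (residue composition, functional-domain content) that a
   random background protein lacks;
2. a uniform random draw from the proteome is an acceptable stand-in for
   non-interactors, provided anything homologous to a known partner is
   excluded (most proteins do not interact with any given target);
3. presence/absence of a domain identifier carries the domain signal —
   copy number and domain order are ignored.

The classifier is a soft-margin SVM with RBF kernel
k(u, v) = exp(−γ‖u−v‖²). The kernel is sometimes printed in the
literature without the square on the norm; libsvm-family implementations
(including scikit-learn's, used here) square it, and that is the default.
The unsquared exponential kernel is available via `squared_kernel=False`
for fidelity experiments.

Class probabilities are Platt sigmoid calibrations fitted on
cross-validated decision values within the training set
(`CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`, the same
construction as libsvm's `-b 1`). Class *calls* come from the uncalibrated
decision function; near the boundary a calibrated probability can
disagree with the call, the same benign quirk libsvm documents.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| identity threshold | 0.70 | redundancy removal and negative-filter cutoff; "more than" is strict, a pair at exactly 0.70 survives |
| alignment scoring | +1 / −1 / −1 | match / mismatch / linear gap, exact Needleman–Wunsch (no k-mer heuristics) |
| C ladder | 2⁻⁴ … 2⁴ | regularization grid |
| γ ladder | 2⁻¹⁰ … 2¹⁰ | kernel-width grid |
| feature counts | {d, d/2, …, 16} | halving ladder from the data dimension d |
| k (folds) | 5 | stratified cross-validation |
| upsample factor | 1 | exact duplication of positives; negatives matched in size |
| call threshold | derived | min calibrated probability of the assigned class over correctly classified training samples, floored at 0.5 |

Sequence identity is defined CD-HIT-style as identical aligned pairs in an
optimal global alignment divided by the shorter sequence length. Among
score-optimal alignments the one with the most identities is used; the
dynamic program therefore maximizes (score, identities) lexicographically,
which is valid because both objectives are additive along an alignment
path. The kernel is a numba routine so proteome-scale cross-filtering runs
in seconds.

## Numerical conventions and tie-breaks

- **F-score degenerate cases**: zero within-class variance with non-zero
  mean separation scores +inf (a perfectly separating, constant-within-class
  feature, ranked first); zero over zero scores 0. Ranking ties break by
  ascending feature index.
- **Grid-search ties** break toward fewer selected features, then smaller
  C, then smaller γ (n_features = 0 counts as the full dimension). All grid
  cells share the same seeded folds so accuracies are comparable.
- **Dedupe determinism**: records are processed longest-first with
  accession as tie-break, so cluster representatives are reproducible.
- **Negative samples** are returned sorted by accession; all sampling uses
  `numpy.random.default_rng(seed)`.
- **Folds**: scikit-learn's shuffled `StratifiedKFold` under a fixed seed.
  With upsampled replicates, stratification is applied at the level of
  source proteins and the replicates expand afterwards, so fold sizes can
  differ by up to the upsampling factor; without replicates they differ by
  at most one. `k` equal to the dataset size is treated as leave-one-out
  (per-class minimums cannot apply to folds of size one).
- **Non-standard residues** are resolved before any analysis: B→D, Z→E,
  J→L, U→C, O→K; X and `*` are dropped, so composition denominators count
  informative residues only. Any other letter is a hard error.
- **Report determinism**: `report.json` is serialized with sorted keys and
  contains no timestamps; stage wall-times go to the log. Reruns with the
  same config and seeds are byte-identical.

## Design choices where the protocol was genuinely open

- **Domain registry provenance**: the indicator registry is the
  lexicographically sorted union of domains over the *whole* training set
  (both classes). Building it from positives only would leave scan-time
  vectors undefined for background-only domains.
- **Feature selection inside CV**: ranking features on the full dataset
  before cross-validating leaks held-out information. The default re-ranks
  inside each training split; `global_selection=True` exists to reproduce
  the optimistic variant.
- **Upsampling**: duplication is exact (no perturbation). By default the
  replicates of one source protein are confined to a single fold;
  `leaky_upsampling=True` lets them straddle folds, which demonstrably
  inflates CV accuracy (≈0.92 → ≈0.997 at factor 5 on the strong preset)
  because every held-out replicate has exact copies in training.
- **Balance**: the negative sample is always matched in size to the
  (possibly upsampled) positive set.
- **Threshold semantics**: the call threshold is derived from the
  probability of the *assigned* class (so correct negatives count), while
  scan ranking uses the probability of the *positive* class. The 0.5 floor
  keeps a badly calibrated model from calling majority-negative scores
  positive.
- **Scan exclusion**: every protein on the user's positive list is excluded
  from the scan (including positives collapsed by redundancy removal — they
  are known partners, not discoveries), along with the sampled negatives.

## The synthetic generator

`protint.synthetic` emulates the four input files — proteome FASTA, domain
TSV, positive list, category map — with plantable signal. Background
sequences are i.i.d. draws from the UniProt/Swiss-Prot average residue
frequencies with lengths uniform on 80–200; positives draw from a
multiplicatively tilted, renormalized frequency vector (the tilt keeps
composition on the simplex at any strength) and carry a set of enriched
domain identifiers at elevated Bernoulli rates. Presets:

- `null`: 50 positives / 200 background, no tilt, all domains at 0.05 in
  both classes — downstream CV accuracy and AUC should sit at chance;
- `weak`: 60/400, cysteine ×1.5, five domains at 0.30 vs 0.05;
- `strong`: 60/400, cysteine ×3, five domains at 0.80 vs 0.05 — the
  pipeline should recover the signal and rank the planted domains at the
  top of the F-score list.

The background pool (400 for the signal presets) is sized so that factor-5
upsampling (300 negatives) retains an eligible pool after homology
filtering.

What the generator does **not** emulate: phylogenetic correlation between
sequences, realistic domain grammar or co-occurrence, length/composition
coupling, annotation noise or incompleteness, and any real biology of a
particular receptor's interactome. Passing tests on synthetic data
therefore demonstrate that the machinery is correct and calibrated — not
that any particular accuracy will transfer to a real proteome snapshot.

One empirical note: the across-repeat accuracy spread of the negative
re-sampling experiment does *not* shrink as the eligible pool grows at
these scales — a small pool forces heavily overlapping samples and hence
*less* variation between repeats. The robustness experiments therefore
check that the spread is bounded, not that it is monotone in pool size.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the presets above for end-to-end checks (≤ 600 training vectors,
≤ 460-protein scans), down-scaled variants (20–30 positives, 50–100
residue sequences) for unit-level tests, and exhaustive-enumeration
oracles limited to sequences of ≤ 8 residues, where full alignment
enumeration is feasible. Within these sizes the full default grid
(9 × 21 × 3 configurations × 5 folds) completes in well under a minute.

## Known limitations

- Exact O(nm) alignments make redundancy filtering quadratic in the number
  of sequences; for proteome-scale *deduplication* (rather than the
  cross-filtering done here) a k-mer-prefiltered tool is the right choice.
- Domain features are presence/absence only; copy number and architecture
  are invisible.
- Negative sampling assumes non-interaction is overwhelmingly the norm; for
  extremely promiscuous targets the negative set will be contaminated and
  specificity estimates optimistic.
- Platt calibration on ~100-sample training sets is coarse; derived
  thresholds are sensitive to the calibration folds at that scale.
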