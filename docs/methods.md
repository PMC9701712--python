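# Methods

## Model

`promoter70` treats sigma70 promoter recognition as binary classification of
fixed 81-bp windows (positions −60…+20 around a transcription start site).
The model assumes nothing about where a window came from: all signal enters
through sequence-derived features. The chain is

1. **PSTNP fit** — from the labeled training set, learn
   `z(i, t) = F⁺(t, i) − F⁻(t, i)`, the per-position difference in relative
   trinucleotide frequency between promoters and non-promoters
   (i = 1…79, t over the 64 trinucleotides; single-stranded variant). Rows
   sum to 0 and entries lie in [−1, 1] by construction.
2. **Encoding** — concatenate, in a fixed documented order, the families
   DNC (16), TNC (64), skews (2), EIIP (64), PSTNP (79), DAC (12), DCC (60),
   DACC (72), MAC (12), NMBAC (12), PC-PseTNC (66), motif counts (2):
   461 named columns under the defaults. All encoders are pure functions of
   (sequence, config[, table]).
3. **Min–max scaling** — `x' = (x − min)/(max − min)` with training-set
   extrema; a training-constant feature maps to 0; held-out values are not
   clipped.
4. **RFE** — recursive feature elimination to 200 features with an
   L2-penalized logistic-regression estimator (C = 1, lbfgs), dropping the
   `min(10, surviving − 200)` lowest-|coefficient| features per round.
5. **Classifier** — default SVM: RBF kernel, inner stratified 5-fold
   accuracy grid over C ∈ {1, 10, 100} × γ ∈ {scale, 0.01, 0.001}, winner
   refit with Platt sigmoid calibration so the reported score is a
   probability in [0, 1]. DT / RF / KNN / XGB / GNB backends share the same
   interface and also report `predict_proba` scores.

Evaluation is stratified five-fold cross-validation. Every fold refits the
complete data-dependent chain (steps 1, 3, 4, 5) on its training folds only;
the per-fold artifacts are retained so this no-leakage property is auditable
(and is audited in the test suite). Reported measures: sensitivity,
specificity and accuracy in percent (2 decimals), MCC and AUROC (3
decimals), per fold plus their arithmetic mean. AUROC uses the trapezoidal
rule with the Mann–Whitney tie convention.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window length | 81 bp | the −60…+20 convention; padding/truncation enforce it |
| lag d_max | 2 | maximum spacing of the autocorrelation families |
| λ, w | 2, 0.05 | PC-PseTNC order factors and their weight |
| dinucleotide properties | Twist, Tilt, Roll, Shift, Slide, Rise | standard helical parameters, standardized to mean 0 / sd 1 across the 16 dinucleotides |
| trinucleotide properties | DNase bendability, nucleosome positioning | standardized across the 64 trinucleotides |
| EIIP | A 0.1260, C 0.1340, G 0.0806, T 0.1335 | published electron-ion interaction pseudopotentials |
| motifs | TATAAT, TTGACA | the two sigma70 consensus boxes |
| RFE target / step | 200 / 10 | working feature set size and per-round elimination |
| threshold | 0.5 | promoter call boundary on the [0,1] score; user-overridable |

Property tables live in `src/promoter70/data/*.tsv` and are plain
tab-separated text; swapping in other indices only requires editing those
files or passing arrays to `EncoderConfig`.

## Synthetic data

The generator emulates the structure the method exploits: positives plant
TTGACA and TATAAT on an A/T-rich i.i.d. background (A+T fraction 0.6), with
the −10 box anchored at window indices 49–54 (offsets −12…−7), a spacer
drawn uniformly from 15–19 bp, and each box base randomized with probability
0.1; negatives are i.i.d. coding-like background with A+T fraction 0.48 and
no boxes. This reproduces the two signals real benchmarks show — global A/T
enrichment of promoters and position-specific consensus elements — and is
deterministic under a seed.

What it does **not** emulate: real genomic background (codon structure,
repeats, skewed k-mer spectra), degenerate or displaced promoter elements,
UP elements and extended −10 motifs, or the class imbalance of curated
benchmarks. Passing the end-to-end tests therefore demonstrates that the
chain recovers a planted compositional + positional signal without leakage —
not that the shipped defaults reach any particular accuracy on real
RegulonDB-derived data, which would require the curated sequences
themselves.

Problem sizes used in the shipped experiments: 300 + 300 windows for the
cross-validated chain, 500-bp fragments for scan localization, one window
(244 evaluations) for design. These sizes give stable estimates for a
generator this strongly structured; larger runs change nothing qualitative.

## Numerical choices

- Zero-denominator conventions: skews return 0 when a base pair is absent;
  MCC is 0 when any marginal is empty; MAC returns 0 when the property
  series is constant (variance below 1e−10 — standardized properties are
  order 1, so this only triggers for homopolymer-like input).
- Property standardization uses the population standard deviation across
  the word alphabet.
- PC-PseTNC output sums to exactly 1 up to rounding; the implementation
  keeps the algebraic form `(f, w·θ)/(1 + w·Σθ)` rather than renormalizing.
- Padding side for short predict-mode inputs is the 3' end, preserving the
  upstream −35/−10 region; scan windows are never padded.
- Ambiguity codes are rejected rather than imputed: every feature formula
  is defined on {A, C, G, T} only, and silent imputation would distort the
  encodings.
- Determinism: one integer seed drives fold splitting, the RFE estimator,
  classifier randomness and the generator; identical seeds give identical
  reports. The Platt calibration uses a fixed internal split, so model
  scores are run-to-run reproducible.

## Design choices

- The published feature inventories of this method family are
  service-defined and not enumerable from their descriptions; this package
  pins configurable family-level defaults (the 461 columns above) instead of
  chasing an exact count — the RFE stage is what fixes the working set.
- Cross-validation is stratified, the standard reading for imbalanced
  promoter benchmarks; the chain is refitted per fold rather than once on
  the full set, trading compute for an honest generalization estimate.
- "All possible mutants" in design mode means all 81 × 3 single-position
  substitutions plus the original (244 records): exhaustive multi-position
  mutagenesis is combinatorially infeasible and single substitutions already
  identify the minimum edits that flip a call. `flip_set` filters the
  label-flipping subset.
- Scan mode slides at stride 1 on the given strand; `--revcomp` adds the
  reverse complement explicitly, with coordinates mapped back to the forward
  strand.
- Model persistence is a joblib archive carrying a format-version string,
  the encoder config, PSTNP table, scaler, selection and fitted classifier;
  loading verifies the version and fails loudly on truncation.

## Known limitations

- Feature computation is per-sequence Python/NumPy; scanning megabase-scale
  genomes is possible but not optimized (≈ milliseconds per window).
- The SVM grid is deliberately small; exotic kernels or broader grids are
  out of scope.
- Scores are calibrated on the training set and should not be read as
  genome-wide posterior probabilities under a different class balance.
- Only the four-letter DNA alphabet is supported; RNA input is accepted via
  U→T mapping but ambiguity codes are errors by design.
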