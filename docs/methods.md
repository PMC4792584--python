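# Methods

This note documents the models, conventions and numerical choices behind
`combotx`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic data do and do not emulate.

## Dose-response fitting

The median-effect relation `fa/fu = (D/Dm)^m` (with `fu = 1 - fa`) is
fitted by ordinary least squares on the linearized coordinates
`(log10 D, log10(fa/fu))`. This is exact on noise-free Hill data — the
property the test suite uses as the fitter's oracle — and matches the
classical median-effect-plot workflow. Conventions:

* **Clamping.** Observed `fa` outside `[1e-4, 1 - 1e-4]` is clamped before
  the log-odds transform; cells at exactly `fa = 0` arising from dose 0 are
  *excluded*, not clamped (log-dose is undefined there). The clamp bound
  `FA_EPS = 1e-4` also marks the upper boundary past which combination
  cells are excluded from CI (a clamped `fa` would give an unbounded
  equivalent dose).
* **Weighting.** Unweighted least squares on the linearized scale — the
  simplest defensible choice. Note the transform is heteroscedastic:
  multiplicative noise on `fa` inflates log-odds noise by `1/(1-fa)`, so
  points near full effect carry most of the error. Calibration designs
  should keep `fa` roughly inside 0.2–0.8 (the classical median-effect
  guidance); with six doses spanning that window and 5% multiplicative
  noise, the 95th-percentile errors are ≈ 0.11 on a unit slope and ≈ 13%
  on `Dm` (measured over 500 simulations). The absolute slope error scales
  with `m` itself, because the dose window mapping to a fixed `fa` range
  compresses as `1/m`.
* **Quality.** `r_squared` is reported on the linearized coordinates,
  mirroring the "r" statistic conventionally quoted alongside
  median-effect fits.
* **3PL.** The 3-parameter logistic `fa = top/(1 + (ic50/D)^h)` fixes the
  bottom asymptote at 0 — a convention, as inhibition data start at zero
  effect by construction. Initialization: `top = max fa`, `ic50` at the
  dose nearest half-max, `h = 1`; bounded trust-region least squares with
  up to 5 deterministic jittered restarts (fixed internal seed). Data whose
  response *decreases* with dose are rejected up front since no positive
  hill slope can represent them. Requires ≥ 4 positive doses spanning at
  least a decade.

## Synergy scoring

* **Bliss.** Expectation `A + B - A*B` from the monotherapy row/column of
  the same matrix; scores are observed minus expected over cells with both
  doses > 0; the Bliss sum totals them. Scores are computed on the
  fractional (0–1) scale; a percent-scale output (×100) is available,
  since published Bliss sums are often quoted on the 0–100 inhibition
  scale.
* **CI.** The two-term (mutually exclusive) Chou-Talalay form
  `CI = D1/Dx1 + D2/Dx2`, the CompuSyn default. The dose matrix is not a
  fixed-ratio design, so CI is computed per cell from that cell's observed
  `fa`; the CI-vs-FA view bins cells into seven FA bins across the 0.2–0.9
  window. The per-matrix verdict is a documented aggregation choice:
  synergy iff the *median* CI over evaluable cells with `fa` in
  [0.2, 0.9] is below 1 (with a 1e-6 numerical tolerance so
  exactly-additive data do not fall on the synergy side of rounding);
  additive in [1, 1.1); antagonism above. Cells at the clamp boundaries
  are excluded from CI, and the exclusion count is reported.
* **Two nulls disagree.** Bliss independence and Loewe additivity are
  different null models: for Hill slopes near 1, Bliss-independent data
  score as Loewe-synergistic (CI < 1), and for steeper slopes (m ≈ 2,
  the generator default) as mildly Loewe-antagonistic. This is a known
  property of the two frameworks, not an artifact; it is why the synergy
  call used in the operating-characteristics tests requires *both* a
  median CI < 1 and a positive Bliss sum.

## RPPA z-scores

Fold changes (treated/vehicle, from already quantile-normalized array
data — the facility's normalization is accepted as input, not
re-implemented) are log2-transformed and standardized per column against
all proteins on that array. The sample (n−1) standard deviation is used,
switchable to the population form. Selection keeps proteins with
`|z| > 1.96` in every required column (both cell lines), ordered by
descending minimum |z|. A pooled mode that shares one reference
distribution across a group of columns is available but experimental; the
per-column form is the default reading of "all proteins of the array". The
low-signal filter threshold is a configuration parameter (default 100
intensity units) — a convention, since no published value exists.

## Expression processing

* **Filter.** Genes with fewer than 5 counts summed over all samples are
  excluded.
* **Upper-quartile normalization.** The 75th percentile
  (linear-interpolation quantile) is computed per sample over genes with a
  nonzero count in at least one sample; all-zero genes carry no depth
  information and are excluded by the standard UQ convention. Scale
  factor = sample p75 / geometric mean of p75s (the geometric-mean anchor
  keeps overall magnitude stable); normalized values are counts divided by
  their factor, then multiplied by one global per-million constant. After
  normalization the per-sample upper quartiles agree to floating
  precision, and a pure library-size multiplier between duplicate samples
  cancels exactly (binary scaling is exact in IEEE arithmetic).
* **Fold changes.** Condition means (single-sample conditions degenerate
  to the sample itself) with a pseudocount (default 0.5) in numerator and
  denominator to tolerate zeros.
* **Regulation threshold.** "1.5-fold regulated" is read as the symmetric
  linear rule: fold change ≥ 1.5 or ≤ 1/1.5. Ranking is by log2 fold
  change, descending, with ties broken by gene identifier so the output is
  independent of input row order.

## GSEA

The weighted running-sum statistic: walking down the ranked list, add
`|s_i|^p / Σ|s|^p` at set members, subtract `1/(N-k)` at non-members; the
enrichment score is the signed extremum. `p = 1` (the "weighted" default)
throughout; the sum always returns to 0 at the end of the walk, which is
asserted in tests. Degenerate cases: a set covering the whole list is an
error; a set whose members all have score exactly 0 under `p > 0` falls
back to uniform hit weights.

* **Preranked null.** Random same-size gene sets drawn from the ranked
  universe (gene-label permutation) — the only null available on a bare
  ranked list. The truncated (post-threshold) universe is used as given.
* **Phenotype null.** Class labels are shuffled and genes re-ranked by
  signal-to-noise `(μA − μB)/(σA + σB)` with the conventional floors
  (σ at least 20% of |mean|, 0.2 absolute when the mean is 0; sample sds,
  ddof 1). When fewer distinct label splits exist than requested
  permutations they are enumerated exhaustively with a warning (fixing the
  p-value granularity); with both classes of size 1 the call falls back to
  gene-set permutation, with a warning.
* **NES / p / FDR.** NES divides ES by the mean |null ES| of matching sign
  (separate positive/negative means, per the original normalization);
  nominal p is the same-sign null tail fraction. FDR q compares the pooled
  normalized null tail beyond a set's NES with the observed tail, clipped
  to [0, 1]; a monotonicity pass then assigns each set the smallest raw
  FDR among same-sign sets with |NES| at most its own (the threshold at
  which it would still be called), so q never increases with |NES|.
* **Size bounds.** Sets overlapping the list in fewer than 5 or more than
  500 genes are skipped by default (standard practice; configurable — the
  synthetic pipelines lower the minimum when ranked lists are short).
* **Determinism.** All permutation draws come from an explicit seeded
  generator; results are bit-reproducible given the seed.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes,
with ground truth attached:

* **Dose matrices.** A 10×5 two-fold grid (a dasatinib-like 0–400 nM axis
  by a CYT387-like 0–3.5 µM axis), Hill slopes of 2 (steep multi-day
  proliferation curves typical of kinase inhibitors), `Dm` mid-grid, and
  multiplicative lognormal noise with 5% CV (plate-reader viability noise
  is scale-proportional; the noise is unit-mean, applied to `fa`, clamped
  to [0, 1], dose-0 cells pinned at 0). Interaction models: Bliss
  independence, Loewe additivity (solved per cell by bisecting the
  equivalent-dose equation to 1e-15), and potency-shift alternatives that
  multiply each agent's `Dm` by a factor inside the combination only
  (0.5 ⇒ synergy, 2 ⇒ antagonism). The replicate structure of real plates
  (means over wells, edge effects, drift) is not simulated.
* **Counts.** Gamma-Poisson (negative-binomial) counts, lognormal baseline
  means, dispersion 0.1, three samples per condition; planted gene sets
  carry a 2-fold expected change in their target condition — comfortably
  above the 1.5-fold threshold, so thresholding retains most planted
  genes under noise. Real library-composition effects, batch structure and
  gene-length biases are not emulated, so passing tests demonstrate the
  normalization/ranking/GSEA *logic*, not robustness to those artifacts.
* **RPPA.** Background log2 fold changes N(0, 0.5); planted outliers are
  displaced deterministically to `sign × z × σ` with 10% jitter in every
  column, so their expected within-array z matches the nominal planting
  level. Antibody cross-reactivity and slide-level artifacts are out of
  scope.

All generator defaults are fixed study conditions, not tuning knobs; every
stochastic operation takes an explicit integer seed and no global random
state is used anywhere.

## Problem sizes

The shipped test and acceptance workloads use 10×5 (and 10×10 sham) dose
matrices, 1 500–2 000-gene count matrices with 3 samples per condition,
200-protein arrays, and 200–1 000 permutations per GSEA run; Monte-Carlo
statements use 100–500 seeded replicates. These sizes give stable
operating-characteristic estimates while keeping any full run in the
seconds-to-minutes range on a single CPU.

## Known limitations

* The three-term (mutually non-exclusive) CI variant, Loewe/ZIP/HSA
  response-surface scores, and leading-edge analysis are not implemented.
* CI aggregation over a non-fixed-ratio matrix has no canonical
  definition; the median-over-window rule here is explicit but is a
  package convention.
* Phenotype-permutation GSEA with very few samples has coarse p-value
  granularity (exhaustive enumeration warns about this); interpret
  small-n results accordingly.
* The expression arm performs no differential-expression testing — fold
  -change thresholds only, by design.
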