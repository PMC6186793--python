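# Methods

## Problem and model

`ncrpi` predicts whether a non-coding RNA and a protein interact, using
nothing but their sequences. The supervised unit is a (protein, ncRNA)
pair with a binary label; the model is a feature-fusion pipeline:

1. **Protein descriptor.** The protein's position-specific scoring matrix
   (PSSM) — the r × 20 log-odds profile produced by iterative database
   search, encoding per-position evolutionary conservation — is treated as
   a grey-level image. Entries are squashed into (0, 1) with a logistic
   transform, the grid is mapped into the closed unit disk, and the
   magnitudes |M_ab| of its pseudo-Zernike moments are collected for
   orders a = 1…alpha_max, repetitions b = 0…a. Moment magnitudes are
   rotation-invariant image descriptors; they compress a variable-length
   profile into a fixed-length vector (65 values at the default
   alpha_max = 10).
2. **RNA descriptor.** The RNA is scanned one nucleotide at a time into
   L−k+1 overlapping k-mer windows; their one-hot indicators stacked give
   a sparse (L−k+1) × 4^k matrix whose column means are exactly the
   normalized k-mer frequencies. The default descriptor is the leading
   right-singular vector of this matrix scaled by σ₁/Σσᵢ (the share of
   spectral mass it carries), sign-fixed so its largest-magnitude entry is
   positive. The plain frequency vector and the concatenation of both are
   available as alternatives (`rna_mode`).
3. **Classifier.** Concatenated protein+RNA vectors feed a LightGBM
   gradient-boosted decision tree with gradient-based one-side sampling
   (GOSS) and exclusive feature bundling; a plain GBDT (both switched
   off) and an RBF SVM with calibrated probabilities are interchangeable
   backends behind the same interface, so classifier comparisons are a
   configuration change.
4. **Evaluation.** Stratified 10-fold cross-validation; per-fold
   accuracy, sensitivity, specificity, precision and MCC at threshold
   0.5; fold-averaged and pooled ROC-AUC.

## Pseudo-Zernike numerics

The basis is V_ab(x,y) = R_ab(ρ)·e^{jbθ} with radial polynomials
R_ab(ρ) = Σ_t Z(a,|b|,t)·ρ^{a−t} and

    Z(a,|b|,t) = (−1)^t (2a+1−t)! / [ t! (a−|b|−t)! (a+|b|+1−t)! ].

Coefficients are evaluated in log-factorial space (finite well past order
30) and verified against exact integer-factorial arithmetic. The basis is
orthogonal over the unit disk with norm π/(a+1); the discrete Gram matrix
on a 400×400 midpoint grid reproduces this within 0.1% for orders ≤ 6,
which is the arbiter for the coefficient form.

**Unit-disk mapping.** Cell (i, j) of the r × 20 grid maps to
x = (2j−19)/D, y = (2i−(r−1))/D with D the half-diagonal
√((r−1)² + 19²): the grid's bounding box is inscribed in the disk (corner
cells at ρ = 1 exactly) and no cell is discarded. Moments are computed by
midpoint quadrature at the grid's own resolution — no resampling, since
the mapping already normalizes scale and interpolation would add an
arbitrary step. On square grids the mapped coordinate set is invariant
under quarter turns, so rotation invariance of |M_ab| holds to machine
precision and is asserted at 1e−9.

**Normalization.** Raw log-odds are unbounded; the logistic transform
1/(1+e^{−p}) bounds them in (0, 1) monotonically, which is the standard
way to turn log-odds into a bounded intensity. A constant profile maps to
a constant 0.5 image.

**Choice of alpha_max = 10.** The descriptor length Σ_{a=1}^{A}(a+1)
grows quadratically; 65 features keeps the protein block comparable in
size to the 256-long RNA block and avoids high-order moments, whose
discrete quadrature degrades fastest on short proteins. Negative
repetitions are omitted since |M_{a,−b}| = |M_{a,b}|.

## RNA layer numerics

The SVD feature is computed from the 4^k × 4^k Gram matrix QᵀQ by
symmetric eigendecomposition — exact for the one-hot window matrix, whose
Gram is the diagonal of k-mer counts — and agrees with a dense SVD to
1e−9 on random matrices. The σ₁/Σσᵢ scale and the sign fix make the
feature deterministic; duplicating every window row rescales all singular
values equally and leaves the feature unchanged. Word size k = 4
(256 columns) is the default; k is configurable.

## GOSS variance gain

The auditable gain statistic keeps A = the ⌈p·n⌉ instances of largest
|gradient| (ties to the lower index) and samples B, of size ⌈q·n⌉, from
the remainder; B's gradient sums are amplified by (1−p)/q, the constant
that makes them unbiased estimates of the full remainder sums under this
size convention (hence q ≤ 1−p; with p = 1, B is empty and the statistic
reduces exactly to the exhaustive variance gain, which is asserted on
every split point of 500 random instances). The Monte-Carlo mean over B
resamplings converges to the exhaustive gain as q approaches its feasible
limit 1−p; the residual discrepancy at q = 0.78, p = 0.2 is ≈2%,
dominated by the n_l/n_r counts being taken over A∪B rather than the full
data, and is checked with split-structured gradients — with pure-noise
gradients the exhaustive gain is near zero and a relative criterion is
ill-posed. Training itself delegates GOSS (and feature bundling) to
LightGBM; the standalone implementation exists so the statistic is
testable in isolation.

Classifier defaults (100 rounds, 31 leaves, learning rate 0.1, GOSS
top/other rates 0.2/0.1, min_child_samples 10) are conventional LightGBM
small-data settings, all overridable. Training is single-threaded and
deterministic given a seed.

## Metrics conventions

Any ratio with a zero denominator (precision with no positive calls, MCC
with a zero factor) is defined as 0 so fold averages remain total. AUC is
the trapezoidal area under the threshold-swept ROC and equals the
Mann–Whitney pairwise-ranking statistic (asserted to 1e−12). Mean metrics
are arithmetic means of the per-fold values, column by column; the pooled
ROC concatenates all held-out scores. Both fold-averaged and pooled AUC
are reported since either convention appears in the literature.
Stratified folds are the default (`--no-stratify` restores plain random
splits) because small corpora otherwise occasionally produce single-class
test folds.

## Synthetic data: what it emulates and what it does not

Real benchmark corpora (hundreds to thousands of pairs extracted from
solved RNA–protein complexes, with negatives built by random re-pairing)
require external downloads and a PSI-BLAST run against a large protein
database, so the package ships a generator that emulates the *shape* of
that data: variable-length sequences (proteins 50–250 aa, RNAs 60–300 nt
by default), PSSM-like profiles, and labels carrying a learnable
sequence-composition signal. Positive pairs draw a fraction
signal_strength/2 of protein residues from the charged sub-alphabet
{K,R,H,D,E} — shifting their profile rows — and overwrite
round(signal_strength·L/16) copies of the hexamer GCGAUC into the RNA —
shifting its k-mer spectrum (~35% coverage at full strength, chosen so
the planted classes are strongly separable, the regime in which an
end-to-end recovery test is informative). At signal_strength 0 positives
and negatives are generated identically.

Synthetic PSSMs are the BLOSUM62 row of each residue plus Gaussian noise
(sd 0.3): a profile whose only conservation signal is composition.
Real profiles contain position-specific conservation that composition
cannot express, and real interactions depend on structure, binding-site
context and homology relationships none of which the generator models —
so passing the planted-signal test shows the pipeline can extract and
classify a compositional signal end-to-end, not that it reaches any
particular accuracy on biological data. The sizes used by the default
checks (600 pairs for the signal run, 5 × 300 for the null, 120 for the
bitwise-reproducibility run) keep a full run in tens of seconds while
leaving the null AUC band [0.4, 0.6] comfortably wider than its sampling
noise.

## Degenerate inputs and tie-breaks

Proteins of length 1 are valid (the disk mapping uses the 20-column
width); RNAs must be at least k long. Unknown residues (X, B, Z,
selenocysteine U) are retained in sequences and given an all-zero
(logistic-neutral) profile row in synthetic PSSMs. k-mer ties in the SVD
feature resolve through the deterministic symmetric eigensolver; GOSS
gradient ties resolve toward the lower index; duplicate pairs, unknown
labels, and alphabet violations are hard errors naming the offending
records.

## Known limitations

- No PSI-BLAST wrapper: real PSSMs must be produced externally and
  supplied as ASCII files (`--pssm-dir`); the parser accepts the standard
  layout.
- The published benchmark corpora are not bundled; replication on them
  requires the original downloads and profile databases.
- No classifier hyperparameters are known for the published comparison
  tables, so those numbers are not exactly recoverable even with the
  datasets; the backends exist to reproduce the comparison's *design*.
- Feature extraction is fit-free by construction, which rules out
  leakage but also excludes learned (e.g. autoencoder) representations.
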