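# ncrpi

Sequence-based prediction of ncRNA–protein interactions.

Most non-coding RNAs act by binding proteins, but solved RNA–protein
complexes cover only a sliver of the known transcriptome, so computational
screening from sequence alone is the practical route to candidate
interactions. `ncrpi` implements a feature-fusion pipeline for exactly
that: given a protein sequence (via its evolutionary profile) and an ncRNA
sequence, it scores the pair's interaction probability with a
gradient-boosted classifier, and evaluates itself by 10-fold
cross-validation. It is aimed at computational biologists who have labeled
pair sets (e.g. pairs extracted from complexes, plus random re-pairing
negatives) and want a reproducible sequence-only baseline.

## Method

- **Protein → pseudo-Zernike moments of the PSSM.** The r × 20
  position-specific scoring matrix P (PSI-BLAST log-odds; p_ij scores
  amino acid j at position i) is logistic-normalized, inscribed in the
  unit disk, and described by the rotation-invariant moment magnitudes

      M_ab = (a+1)/π ∬ f(x,y) V*_ab(ρ,θ) dx dy,
      V_ab = R_ab(ρ) e^{jbθ},
      R_ab(ρ) = Σ_t (−1)^t (2a+1−t)! / [t!(a−|b|−t)!(a+|b|+1−t)!] · ρ^{a−t},

  giving F_protein = [|M_10|, |M_11|, …, |M_{A,A}|] (65 features at the
  default order bound A = 10).
- **ncRNA → k-mer matrix + SVD.** The sequence over {A,C,G,U} is scanned
  one nucleotide at a time into a sparse (L−k+1) × 4^k one-hot window
  matrix Q (column means = normalized k-mer frequencies); from Q = UΣVᵀ
  the leading right-singular vector scaled by σ₁/Σσᵢ is the 4^k-long
  descriptor (k = 4 by default; plain frequencies or both available).
- **Classifier.** Concatenated features feed LightGBM with gradient-based
  one-side sampling (GOSS) and exclusive feature bundling; plain GBDT and
  an RBF SVM are drop-in backends. The GOSS estimated variance gain
  V(b) = 1/n·[(Σ_{A_l}g + (1−p)/q·Σ_{B_l}g)²/n_l + (Σ_{A_r}g +
  (1−p)/q·Σ_{B_r}g)²/n_r] is also implemented standalone as an audited,
  tested operation.
- **Evaluation.** Stratified 10-fold CV; accuracy, sensitivity,
  specificity, precision, MCC (zero-denominator ratios defined as 0) and
  trapezoidal ROC-AUC, which is asserted equal to the Mann–Whitney
  pairwise-ranking statistic.

See `docs/methods.md` for numerical conventions, defaults and known
limitations.

## Worked example

Generate a synthetic 200-pair dataset with a planted compositional signal
(positive-pair proteins biased toward charged residues, positive-pair RNAs
carrying a repeated hexamer motif), then cross-validate:

```sh
ncrpi synth --n-pos 100 --n-neg 100 --seed 7 --out-dir demo/data
ncrpi cv --proteins demo/data/proteins.fasta --rnas demo/data/rnas.fasta \
         --pairs demo/data/pairs.tsv --seed 7 --out-dir demo/cv
```

which logs

```
INFO ncrpi: wrote dataset with 200 pairs to demo/data
INFO ncrpi: cv done: mean accuracy 0.9800, pooled AUC 0.9991
```

and writes `demo/cv/report.json` with the per-fold and mean metrics:

```
mean: {'accuracy': 0.98, 'mcc': 0.9609, 'precision': 0.9809,
       'sensitivity': 0.98, 'specificity': 0.98}
pooled_auc: 0.9991   mean_fold_auc: 0.9990
```

The near-perfect numbers say the pipeline recovers the planted signal —
every stage from profile featurization to fold-wise scoring is working —
not that real complexes are this easy; with `--signal-strength 0` the same
pipeline hovers at AUC ≈ 0.5, as it must when labels carry no information.
Real protein profiles go in as PSI-BLAST ASCII files via
`--pssm-dir` (one `<id>.pssm` per protein); without it, profile-shaped
synthetic PSSMs are generated from residue substitution rows. The other
subcommands are `extract-features`, `train` and `predict` (`ncrpi --help`).

As a library:

```python
from ncrpi import synthesize_dataset, cross_validate

report = cross_validate(synthesize_dataset(100, 100, seed=7), seed=7)
print(report.mean_metrics)
print(report.pooled_roc.auc)
```

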