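# pnesent

Entropy-based analysis of interictal EEG/ECG for differentiating
**psychogenic non-epileptic seizures (PNES)** from **epilepsy**.

PNES events clinically resemble epileptic seizures but are not caused by
epileptiform brain activity, and they are routinely misdiagnosed for years.
Between seizures the EEG of the two conditions looks normal to visual
inspection, but its *complexity* may differ. This package implements a
complete, testable version of that analysis for signal-processing and
machine-learning researchers working on seizure-disorder biomarkers:

* **Six entropy estimators**, implemented from scratch and verified against
  independent brute-force oracles — approximate entropy ApEn(m, r), sample
  entropy SampEn(m, r) = −ln(A^m(r)/B^m(r)), Welch-spectrum spectral
  entropy −(1/ln Ω)Σpᵢ ln pᵢ, SVD entropy of normalised squared singular
  values of a delay embedding, order-2 Rényi entropy
  (1/(1−α))·log₂ Σpᵢ^α of the amplitude histogram, and Morlet wavelet
  entropy −Σp_j ln p_j of relative scale energies.
* A **preprocessing chain** from raw multichannel recordings (EDF or
  in-memory) to banded, artifact-screened, baseline-corrected 10-s epochs:
  resampling to 256 Hz, zero-phase FIR 0.5–40 Hz, Bessel-filtered ECG lead
  derivation, epoching, amplitude-criterion rejection, and decomposition
  into delta/theta/alpha/beta/gamma bands (21 features per band per epoch:
  20 scalp channels + ECG).
* An **imbalance-aware classification protocol**: epoch-wise stratified
  10-fold CV with per-fold z-scoring → SMOTE → PCA (95 % variance) →
  {RBF-SVM, kNN with inner k-search, random forest, gradient boosting},
  scored by precision, recall and balanced accuracy
  ½(TP/(TP+FN) + TN/(TN+FP)) with PNES positive.
* **Grouped permutation band importance** i = s − (1/K)Σₖ s̃ₖ and a
  leave-one-band-out exclusion experiment.
* A **synthetic cohort generator** with planted, configurable class
  contrasts (band-specific oscillation amplitude, spectral exponent, RR
  jitter), so the entire pipeline is exercisable and testable without any
  clinical data.

See `docs/methods.md` for the model details, parameter defaults, and what
the synthetic data does and does not emulate.

## Worked example

Generate a 10 + 10 subject cohort (20 ten-second epochs each) with a strong
planted theta-band contrast, extract Rényi entropy in all six bands, and
classify with kNN under the full protocol:

```python
from pnesent import (CohortConfig, ClassifierSpec, generate_cohort,
                     preprocess_cohort, extract_features, run_cv,
                     band_exclusion_experiment)

cfg = CohortConfig(n_pnes=10, n_epilepsy=10, epochs_per_subject=20, seed=1)
banded, rejection_log = preprocess_cohort(generate_cohort(cfg))
features = extract_features(banded, "renyi")      # 400 epochs x 126 features
cv = run_cv(features, ClassifierSpec(kind="knn"), folds=10, seed=1)
print(f"balanced accuracy {cv.mean_balanced_accuracy:.3f}  "
      f"precision {cv.mean_precision:.3f}  recall {cv.mean_recall:.3f}")

table = band_exclusion_experiment(features, ClassifierSpec(kind="knn"),
                                  folds=10, K=10, seed=1)
print(table.round(3).to_string(index=False))
```

Output:

```
balanced accuracy 1.000  precision 1.000  recall 1.000
band_excluded  precision  recall  balanced_accuracy  band_importance
        broad      1.000   1.000              1.000            0.003
        delta      1.000   1.000              1.000            0.000
        theta      0.932   0.975              0.950            0.172
        alpha      1.000   1.000              1.000            0.001
         beta      1.000   1.000              1.000            0.000
        gamma      0.995   1.000              0.997            0.001
         none      1.000   1.000              1.000              NaN
```

The planted theta contrast is fully separable (balanced accuracy 1.000 on
the "none" row). Excluding theta produces the largest accuracy drop (to
0.950 — the drop is moderate because the broad band, which contains the
theta oscillation, is still present) and theta dominates the permutation
importance (0.172 vs ≤0.003 for every other band): the pipeline recovers
exactly the structure that was planted. With the contrast switched off
(`cfg.with_null_contrast()`) the same pipeline scores at chance.

The same stages are available from the command line:

```bash
pnesent synth --out cohort/ --seed 1 --n-pnes 3 --n-epilepsy 2 --epochs 2
pnesent classify --measure renyi --bands all --clf knn --seed 1
pnesent importance --measure renyi --clf knn --seed 1
pnesent run-all --out results/ --seed 1
```

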