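# histodti

Quantitative pipeline linking in vivo diffusion-tensor imaging (DTI) to
histological tissue microstructure in a rat model of status-epilepticus
(SE) brain damage. The package reimplements the full analysis chain for
studies that ask *how well do in vivo DTI parameters predict what the
histology shows?* — from micrograph quantification to cross-validated
multivariate modelling — and ships synthetic-data generators so every stage
runs and is testable without any image downloads.

## What it computes

**DTI scalar metrics** from tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃:
MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2, FA, and the trace-normalised
Westin shape indices CL = (λ₁−λ₂)/T, CP = 2(λ₂−λ₃)/T, CS = 3λ₃/T
(T = trace), which satisfy CL + CP + CS = 1 and AD = 3·MD − 2·RD.

**Histological parameters** per region of interest:

- *cell density* (CD, cells/mm²) by automated counting of dark Nissl-stained
  somata (flatten → threshold → components → watershed split);
- *anisotropy index* (AI) of myelin- and GFAP-stained texture from the 2D
  structure tensor (Gaussian-derivative gradients, 11 px kernels, σ = 3 px),
  AI = (μ₁−μ₂)/(μ₁+μ₂) per pixel, averaged over the ROI;
- *astrocyte skeleton morphometry* from GFAP micrographs: a preprocessing
  cascade (bandpass 3–40 px, rolling-ball 200 px, rescale 10–254, unsharp
  σ = 1.5 / weight 0.6, despeckle, region-specific thresholds, binary
  clean-up), topology-preserving thinning, and AnalyzeSkeleton-style
  metrics — branches, total/average branch length, slab/junction/endpoint
  voxels, junctions, triple and quadruple points — with a 0.7 µm cut-off
  that discards bare two-endpoint fragments.

**Statistics**: Cohen's d (SE vs control, pooled SD) with BCa bootstrap 95%
CIs, studentised (Welch-t) two-sided permutation tests (100,000 permutations,
exhaustive at small n), and Benjamini–Hochberg FDR within each reporting
family.

**Predictive model**: for each histological parameter y over animals k and
regions j, the pooled regression y_kj = bᵀx_kj + c + e_kj with
x = (FA, RD, MD, CP, CS) (AD and CL are excluded — including them makes the
design singular and raises an error naming the identity), Pearson
correlation grids, and leave-one-animal-out / leave-one-region-out
cross-validation reporting the held-out correlation R and

    Q² = 1 − mean((y − ŷ)²) / mean((y − ȳ)²),

where Q² ≤ 0 means the model predicts held-out data no better than the mean.

## Worked example

```python
import numpy as np
from histodti.phantoms import CohortSpec, generate_cohort
from histodti.model import fit_multivariate, loao_cv

table = generate_cohort(CohortSpec(seed=1))      # 17 animals x 4 regions
fit = fit_multivariate(table, "AI_myelin", seed=1)
cv = loao_cv(table, "AI_myelin")
print(f"R2={fit.R2:.3f} adj={fit.R2_adj:.3f} F={fit.F:.1f} "
      f"R_cv={cv.R_cv:.3f} Q2={cv.Q2:.3f} n={fit.n}")
```

prints

```
R2=0.803 adj=0.787 F=50.4 R_cv=0.870 Q2=0.755 n=68
```

The synthetic cohort plants a known linear DTI→histology relation with noise
calibrated to a population R² of 0.8; the fit recovers that explanatory
power (R² = 0.80 on 68 rows), and leave-one-animal-out cross-validation
confirms genuine predictive value (R_cv = 0.87, Q² = 0.75). On a null cohort
(no relation) the same code returns Q² < 0 — cross-validation does not
reward overfitting.

The same stages are available from the shell:

```bash
histodti simulate cohort --out out/ --seed 1
histodti model fit  --table out/cohort.csv --response AI_myelin
histodti model loao --table out/cohort.csv --response AI_myelin
histodti run-all --out out/run --seed 1      # full synthetic pipeline
```

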