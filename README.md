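# phconnectome

Multimodal sparse brain-network construction and persistent-homology
quantification for two-group (e.g. risk-allele carrier vs non-carrier)
resting-state studies.

## The problem

Pairwise-correlation functional connectivity ignores both multi-region
co-activation and the white-matter scaffold, and sparse-regression networks
depend on an arbitrary regularization level. This package implements a
framework that addresses all three issues:

1. **Fused multimodal network.** Each region's BOLD series `x_i` is
   regressed on all other regions:

   ```
   min_β ½‖x_i − Σ_{j≠i} x_j β_ji‖² + λ₁ Σ_{j≠i} D_ji |β_ji|
         + (λ₂/2) Σ_{(u,v)} |β_ui − β_vi|
   ```

   with structural weights `D_ji = exp(−ρ_ji²/σ)` (streamline weight
   `ρ_ji`): strong anatomical connections make the corresponding functional
   edge cheap. The last term is a generalized fused lasso that shrinks
   coefficient differences. Solved per column by ADMM; the λ₂ = 0 case runs
   through coordinate-descent lasso paths.

2. **Multiscale integration.** Instead of picking one λ₁, the binary network
   support is computed over a uniform grid λ₁ ∈ [0, 0.9]; edge appearance
   probabilities `p_ij` become filtration distances `d_ij = √(1 − p_ij²)`.

3. **Persistent homology.** A graph filtration (`d_ij < ε`, ε ∈ [0, 1])
   tracks connected components (β₀ bars = single-linkage merge heights; the
   smoothed component curve is fitted with an order-4 B-spline under a
   roughness penalty) and independent cycles of the clique complex (β₁ bars,
   persistence landscapes, and per-subject frequency networks built from
   representative cycles).

4. **Statistics and patterns.** Graph metrics (LE/BET/GE/CCO) are compared
   by t-tests, persistent-homology features by label-permutation tests
   (statistic: distance between group-mean curves/landscapes), subject-level
   discriminability by DWG/DBG distance panels, and group-specific loop
   structures are extracted from thresholded frequency-network differences
   via a minimum cycle basis.

A fully controllable synthetic-data generator (modular structural networks
with streamline-like heavy-tailed weights, BOLD series whose spatial
covariance follows a degree-normalized walk-sum of the structural network,
and a planted group attenuation of within-module coupling) makes every stage
testable without access-restricted imaging data.

## Worked example

```python
import phconnectome as ph

spec = ph.CohortSpec(n_carriers=8, n_noncarriers=8, n_rois=16,
                     n_timepoints=120, n_modules=4, effect_size=0.8, seed=1)
records = ph.generate_cohort(spec)
comparisons = ph.cohort_group_tests(records, n_lambda1=20, lambda2=0.0,
                                    n_perm=199, seed=1)
for c in comparisons:
    print(f"{c.measure:5s} {c.method:12s} p={c.p_value:.4f}")
```

prints

```
LE    t_test       p=0.0000
BET   t_test       p=0.1284
GE    t_test       p=0.0000
CCO   t_test       p=0.0000
PH-0  permutation  p=0.0300
PH-1  permutation  p=0.4700
```

The planted carrier effect (80 % attenuation of within-module functional
coupling) is detected by the efficiency/clustering t-tests and by the PH-0
permutation test (p = 0.03 ≤ 0.05); PH-1 is less sensitive at this cohort
size, mirroring the usual ordering of these measures. With
`effect_size=0.0` all p-values are null-calibrated (uniform over replicate
cohorts).

The same pipeline is scriptable from the shell:

```
phconnectome synth --out cohort/ --seed 1 --n-rois 16 --n-timepoints 120
phconnectome fit   --manifest cohort/manifest.csv --out fit/ --n-lambda1 20
phconnectome ph    --distances fit/ --out ph/
phconnectome all   --config config.yaml --out runs/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a seeded synthetic cohort, runs the complete pipeline (network
construction → λ₁ sweep → integration → persistent homology → group
statistics → pattern extraction), prints the group-comparison table it
computed, and writes the results JSON to `--out`.
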