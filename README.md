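# meditfc

Prefrontal EEG functional connectivity of meditation cohorts: simulation,
feature extraction, group statistics and cross-validated classification.

## The problem

Meditation practice is associated with stronger functional connectivity in
the prefrontal cortex. Given multichannel EEG recorded from long-term
meditators (LTM), short-term meditators (STM) and non-meditators (NM) in
four session states — baseline, meditation, transmission (meditation with
a trainer) and post — the question is whether inter-hemispheric prefrontal
connectivity features can discriminate the groups, and which classifier
family does it best.

`meditfc` implements that analysis as a tested pipeline over 20 prefrontal
channels (10 per hemisphere) in the four canonical EEG bands
(delta 0.3–4 Hz, theta 4–8 Hz, alpha 8–12 Hz, beta 12–30 Hz):

1. **Connectivity** per channel pair *(i, j)*:
   Pearson correlation `Cor(i,j) = Cov(i,j) / sqrt(Var(i) Var(j))` and the
   phase-locking value `PLV(i,j) = |1/L · Σ_t exp(j·Θ_ij(t))|`, where
   `Θ_ij(t)` is the instantaneous (Hilbert) phase difference and `L` the
   number of phase samples.
2. **Graph metrics** on the weighted connectivity graph: the Onnela
   weighted clustering coefficient
   `C_j = 2/(k_j(k_j−1)) · Σ_{k<l} (w_jk·w_jl·w_kl)^{1/3}` (local
   segregation) and the characteristic shortest-path length via Dijkstra
   with edge distance `d = 1/w` (inverse proxy for global efficiency).
3. **Features**: per 10 s epoch, the mean of each measure over the
   10 × 10 inter-hemispheric block (`r`, `plv`) plus `cc` and `sp`,
   arranged into state-wise (measure × band) or band-wise
   (measure × state) 16-column tables.
4. **Statistics and classification**: Welch comparisons of subject-level
   means with significance stars, and 10-fold cross-validated accuracy for
   six classifiers (DT, LDA, LR, SVM, KNN, bagged-tree ensemble) on
   LTM vs NM and STM vs NM, with subject-level folds to prevent leakage.

Because no public recordings exist for this design, the package ships a
**synthetic cohort generator**: per state and band, all channels share a
common narrowband component mixed as `x = κ·common + (1−κ)·private`, so
the coupling strength κ (configurable per group, state and band) directly
controls the inter-hemispheric correlation and PLV the pipeline should
recover.

## Worked example

```python
from meditfc import (SynthConfig, generate_cohort, extract_cohort_features,
                     comparison_grid, run_full_comparison)

config = SynthConfig(  # defaults: LTM 13 / STM 11 / NM 10 subjects, 250 Hz
    state_durations={"baseline": 60.0, "meditation": 60.0,
                     "transmission": 60.0, "post": 60.0},
    seed=0,
)
features = extract_cohort_features(generate_cohort(config))
print(features.groupby(["group", "state"])[["r", "plv", "cc", "sp"]].mean().round(3))
```

```
                        r    plv     cc     sp
group state
LTM   baseline      0.491  0.414  0.410  2.591
      meditation    0.833  0.742  0.742  1.362
      post          0.590  0.499  0.496  2.098
      transmission  0.888  0.810  0.810  1.243
NM    baseline      0.060  0.131  0.118  8.495
      meditation    0.302  0.264  0.256  4.229
      ...
```

Connectivity (r, PLV, CC) rises and path length (SP) falls during
meditation and transmission relative to baseline, more so for meditators —
exactly the structure the default coupling map plants. On top of these
features, `comparison_grid(features)` yields the 192-row star table and
`run_full_comparison(features, seed=0)` the 84-row accuracy grid.

The same analysis, as numbered drivers that save their tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py        # cohort -> scratch/cohort/
python analysis/02_connectivity_features.py  # epochs -> features
python analysis/03_group_comparisons.py      # Welch grid with stars
python analysis/04_classification.py         # 6 classifiers x 14 tables
```

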