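# metastate

Classification of metabolic brain states — hunger versus satiety — from
resting-state fMRI, as a tested, reusable pipeline.

Whether a single resting-state scan carries enough information to tell a
hungry brain from a satiated one is a multi-voxel pattern analysis (MVPA)
question: extract voxel-wise measures of spontaneous BOLD activity, average
them over an anatomical atlas, and ask a classifier which regions
discriminate the two states.  `metastate` implements that analysis end to
end for a paired design (each subject scanned once per condition) and, since
no public raw data exist for this design, ships a synthetic BOLD cohort
generator with known ground truth so every stage is testable.

The package is aimed at researchers who want to study the *behavior* of this
analysis — feature definitions, wrapper selection, permutation inference —
under controlled conditions, not at preprocessing real scanner data.

## The analysis

Three voxel-wise features summarize a band-limited (0.01–0.08 Hz) BOLD
series x_i(t):

- **ReHo** (regional homogeneity): Kendall's coefficient of concordance over
  the K = 27 series of a voxel's 3×3×3 neighborhood,

      W = (Σᵢ Rᵢ² − n·R̄²) / ((1/12) K² (n³ − n)),

  where r_ij ranks time point i within voxel j, Rᵢ = Σⱼ r_ij, and n is the
  series length (170 time points at TR = 2 s in the reference design).
- **DC** (degree centrality): the number of other masked voxels j with
  Pearson correlation r_ij ≥ 0.25 (self-connection excluded), i.e. the
  voxel's degree Dᵢ = Σ_{j≠i} 1[r_ij ≥ 0.25] in the thresholded correlation
  graph.
- **fALFF**: the summed amplitude spectrum (√ power) over 0.01–0.08 Hz
  divided by the summed amplitude over the full band (0, 0.25 Hz]; computed
  on *unfiltered* data.

Each map is averaged over the 90 regions of the AAL atlas (cerebellum
excluded) into a region vector R[1..90], giving a 48 × 90 table (24 subjects
× 2 conditions).  Region subsets are then selected by sequential forward
selection (SFS) or sequential forward floating selection (SFFS), both driven
by the leave-one-out cross-validated misclassification rate of a linear
soft-margin SVM, and significance is assessed by recomputing the error under
within-subject label permutations:

    p = (1 + #{null ER ≤ observed ER}) / (1 + n_perm).

## Worked example

```python
import metastate as ms

# a 24-subject paired cohort with 5 truly informative regions (d = 1.5)
table, truth = ms.simulate_feature_table(
    n_subjects=24, n_regions=90,
    informative_regions={5, 17, 45, 50, 56},
    effect_size=1.5, seed=1000)

trace = ms.sffs(table, max_k=10)
print("selected:", trace.final_subset, "LOOCV error:", round(trace.final_criterion, 3))

cm = ms.loocv_confusion(table, trace.final_subset)
print("confusion [TP FP; FN TN]:", cm.as_array().tolist())
print(ms.metrics(cm).display)

perm = ms.permutation_test(table, trace.final_subset, n_perm=999, seed=7)
print("p =", round(perm.p_value, 4))
```

prints

```
selected: (13, 17, 45, 47) LOOCV error: 0.021
confusion [TP FP; FN TN]: [[23, 0], [1, 24]]
{'ca_pct': 98, 'sen_pct': 96, 'spe_pct': 100, 'er': 0.02}
p = 0.001
```

The selected four-region subset mixes two truly informative regions (17, 45)
with two lucky noise regions — wrapper selection at 48 samples overfits its
own criterion, which is why the package also provides a `full_pipeline`
permutation mode (selection re-run inside every permutation) and
subject-level cross-validation folds; see `docs/methods.md`.  The p-value
here is computed post-selection on the same data and is therefore
anti-conservative — a bias the test suite demonstrates explicitly.

The same analysis runs end to end from the shell, from raw synthetic volumes
to the summary report:

```bash
metastate run-all --preset study2019 --seed 0 --out results/study
metastate extract --preset smoke --seed 1 --out results/smoke
```

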