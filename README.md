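# syntaxconn

Task-induced functional connectivity of syntax-related cortical
networks, rebuilt as a tested, reusable pipeline with a fully seeded
synthetic BOLD cohort.

## The problem

Sentence comprehension engages a set of left-lateralized frontal,
temporal and parietal regions that organize into a small number of
connectivity networks. Under higher syntactic load, the coupling
between these regions reorganizes: local cross-frontal connectivity is
enhanced while the long-range dorsal and ventral frontal–temporal
pathways are suppressed, and this reorganization is reproducible across
healthy controls and patient groups with frontal gliomas. Detecting
that pattern requires estimating *direct* region-to-region coupling
(partial correlation, not plain correlation), partitioning region
pairs by network membership, and comparing whole connectivity matrices
across groups with rank statistics.

This package implements that analysis end to end for researchers
working with task fMRI region time series:

* **Region catalog** — 25 regions with MNI peak coordinates grouped
  into four networks (I: 8, II: 6, III: 5, IV: 6 regions; 14 "core"
  plus 11 additional regions), with every unordered pair classified as
  within-network or between-network (27 within / 64 between for the 14
  core regions; 300 pairs in total for all 25).
* **Sphere-ROI extraction** — voxel-center, inclusive-radius 6-mm
  spheres over the image affine; per-run, per-region z-scoring; run
  concatenation (6 × 128 = 768 volumes per participant).
* **Connectivity** — regress-out partial correlation: for a pair
  (i, j), every other region (plus optional confounds, always with an
  intercept) is removed from both series by OLS and r is the Pearson
  correlation of the residuals. In the population this equals
  `rho_ij·rest = −Ω_ij / sqrt(Ω_ii Ω_jj)` for the precision matrix
  Ω = Σ⁻¹; the precision route is kept as an independent numerical
  oracle. Participant matrices are averaged entrywise on the raw r
  scale into group matrices.
* **Group comparison** — intergroup similarity as Spearman's R_S over
  the r-values of a pair subset (within / between / all); edge flags
  for enhancement (r > 0.20 in every compared group) and suppression
  (reference r > 0.20 and r ≤ 0.20 in every target group);
  network-membership Wilcoxon rank-sum tests (specificity and
  sensitivity of a network's within-block r-values); paired and
  unpaired t-tests on error rates and response times.
* **Synthetic cohort** — the study design (6 runs × 128 volumes at
  TR = 2 s; 32 trials per run, 4 per each of 8 sentence conditions,
  6-s stimulus + 2-s blank; groups of 16/9/9) with region series drawn
  as AR(1)-filtered Gaussian innovations from planted two-state
  precision matrices, an HRF-convolved task signal, and measurement
  noise — so every recovery claim is checked against known ground
  truth. Series can be rendered into 4D volumes to exercise the sphere
  extraction end to end.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the
synthetic cohort (library functions in `src/syntaxconn/` do all the
work; each script writes its tables under `results/`):

```bash
python analysis/01_catalog_partition.py
python analysis/02_simulate_cohort.py      --seed 1
python analysis/03_connectivity_matrices.py --seed 1                 # combined state
python analysis/03_connectivity_matrices.py --seed 1 --state easier
python analysis/03_connectivity_matrices.py --seed 1 --state harder
python analysis/04_group_comparison.py     --seed 1
python analysis/05_recovery_suite.py       --seed 1
```

`04_group_comparison.py` prints, for seed 1:

```
normal vs lpmc_f3 [within ]: R_S = +0.93 (n = 68, p = 1.6e-29)
normal vs lpmc_f3 [between]: R_S = +0.71 (n = 232, p = 3.1e-37)
enhanced between-network edges (all groups r > 0.2): [('L_F3op/F3t', 'L_LPMC'),
  ('L_F3op/F3t', 'L_F3t')]  (planted: [('L_F3op/F3t', 'L_LPMC'), ('L_F3op/F3t', 'L_F3t')])
suppressed within-network edges: [('L_LPMC', 'L_AG'), ('L_F3t', 'L_pSTG/MTG')]
  (planted: [('L_LPMC', 'L_AG'), ('L_F3t', 'L_pSTG/MTG')])
normal paired harder-easier [error]: t(15) = 6.6, p = 9.1e-06, mean diff = +13.2
```

Reading: the two groups were simulated from one shared generative
structure, and their group matrices agree in rank order (R_S = 0.93
over the 68 within-network pairs) even though each participant's
matrix is estimated from only 768 volumes. The two planted
load-enhanced cross-frontal edges and the two planted load-suppressed
pathway edges are recovered exactly, and the planted +15 % error-rate
load effect is detected by the paired t-test at n = 16.

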