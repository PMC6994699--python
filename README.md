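# mitoscreen

Screenable phenotyping of mitochondrial morphology and membrane
potential in primary fibroblasts, re-implemented as a tested Python
pipeline with a built-in synthetic-microscopy simulator.

High-content screens of patient fibroblasts image three channels per
well — Hoechst (nuclei), TMRM (mitochondria; fluorescence reports
membrane potential Ψm), CellMask deep red (plasma membrane) — and ask
whether mitochondrial shape and depolarization resistance separate a
disease group (e.g. idiopathic Parkinson's disease) from controls.
`mitoscreen` provides every computational stage of that assay:

1. **Segmentation** (`mitoscreen.segment`) — nuclei by Gaussian
   low-pass (10×10, σ=2) and a fixed >100 threshold with a 500-px size
   filter; cell area and mitochondria by difference-of-Gaussians
   band-pass with 200-px / 6-px size filters (all filters strict
   "fewer than N removed"); touching cells split by iterative
   grey-tone erosion (disk radius 12) validated by nucleus counting.
2. **Morphometrics** (`mitoscreen.morphometrics`) — per mitochondrion:
   volume (pixel area), subtraction-defined perimeter and erosion
   bodies (radius-1 disk), thinning skeleton with nodes (≥3
   neighbours), endpoints (1 neighbour) and node degree, form factor
   perimeter²/(4π·area), moments-ellipse aspect ratio, and TMRM
   intensities; unweighted means per cell and per subject (subjects
   under 175 cells flagged).
3. **Statistics** (`mitoscreen.stats`) — distribution-adaptive
   two-group tests (Shapiro–Wilk → Welch t; Cabilio–Masaro + Mira
   symmetry tests → Mann–Whitney U; otherwise permutation test, 10⁷
   resamples at full scale, exact enumeration when feasible),
   Fisher's exact test, Bonferroni correction, Pearson correlation
   categories with average-linkage clustering, OLS regression of TMRM
   on morphology + diagnosis, age, gender, and doubling-time
   computation.
4. **Classification** (`mitoscreen.classify`) — linear SVM (C=1),
   leave-one-subject-out cross-validation, pooled-score ROC, AUC with
   the exact Mann–Whitney identity cross-check; baseline-only versus
   baseline+FCCP feature modes.
5. **Simulator** (`mitoscreen.simulate`) — seeded 16-bit 3-channel
   tiles with pixel-exact ground truth masks: mitochondria grown as
   Galton–Watson trees whose branch/endpoint counts are exact by
   construction, plus a fast structure-level cohort sampler with the
   case/control effect structure (fragmentation at conserved total
   mass, reduced branching, elevated TMRM retention under FCCP).

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

Simulate a 20 + 20 subject cohort (200 cells each, baseline and FCCP),
aggregate to subjects, test the fragmentation signature and classify:

```python
from mitoscreen import classify as cl, morphometrics as mm
from mitoscreen import simulate as sim, stats as st

cfg = sim.SimulationConfig(seed=0)
cells = sim.simulate_cohort_features(cfg, n_case=20, n_control=20,
                                     cells_per_subject=200)
subjects = mm.aggregate_subjects(cells, min_cells=175)
base = subjects[subjects.condition == "baseline"]

res = st.compare_groups(base, ["MitoCount", "MitoVolumeMean",
                               "MitoVolumeTotal", "MitoSkel"], seed=0)
print(res[["feature", "test", "p_value", "p_bonferroni"]])

rb = cl.classify_subjects(subjects, "baseline", seed=0)
rc = cl.classify_subjects(subjects, "baseline+FCCP", seed=0)
print(cl.compare_modes(rb, rc))
```

Output:

```
        feature         test      p_value  p_bonferroni
      MitoCount      welch_t 1.166631e-17  4.666524e-17
 MitoVolumeMean      welch_t 4.491775e-20  1.796710e-19
MitoVolumeTotal mann_whitney 9.676346e-01  1.000000e+00
       MitoSkel      welch_t 3.352177e-20  1.340871e-19
{'auc_baseline': 1.0, 'auc_combined': 1.0, 'delta_auc': 0.0, 'n_subjects': 40}
```

Read: the case group has more mitochondria (`MitoCount` up) that are
individually smaller (`MitoVolumeMean` down) and less branched
(`MitoSkel` down) while total mitochondrial mass per cell is unchanged
(`MitoVolumeTotal` non-significant) — fragmentation without net mass
change — and the subject-level feature vectors separate the groups
perfectly under leave-one-out cross-validation at this effect size.

## Command line

```bash
mitoscreen simulate --out cohort/ --n-case 2 --n-control 2 --seed 1
mitoscreen run-all --input cohort/ --out results/ --seed 1
# or end-to-end on a freshly simulated cohort:
mitoscreen run-all --out results/ --seed 1
```

`run-all` writes per-cell and per-subject feature CSVs, group test
results, a classification report, and a manifest (config hash, seed,
version). Individual stages are available as `segment`, `features`,
`stats`, and `classify`; every stage is byte-reproducible for a fixed
seed and config.

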