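# seropanel

Biomarker-panel selection for case-control protein-microarray autoantibody
profiling. The pipeline reads GenePix GAL/GPR files, preprocesses spot
intensities into a log2 feature × sample matrix, and selects a panel of
case-elevated antibody reactivities by repeated resampling:

1. **Stratified split** — a random test set (6 + 6 by default) is held out;
   the remainder (14 + 14) trains the selection.
2. **M-score preselection** — each feature is scored by the minimum, over
   intensity cutoffs, of the hypergeometric upper-tail probability of the
   case/control counts above the cutoff (one-sided, case-high); the 300
   best features are forwarded.
3. **Gene shaving** — random-forest backward elimination: repeatedly drop
   the 20% least-important features, track out-of-bag error, and keep the
   smallest set within one standard error of the minimum OOB error.
4. **Subrun verification** — a fresh forest on the surviving features is
   scored on the held-out test samples.

Steps 1–4 are repeated (100 subruns by default); features selected in at
least 10% of the subruns form the final panel (at most 20 features). The
fixed panel is then verified with 100 redrawn-split random-forest
classifications (accuracy / sensitivity / specificity, cases positive), and
independently re-ranked with a nearest-shrunken-centroids model. The panel
report lists, per feature: raw-scale group medians, selection frequency,
NSC rank position, and whole-cohort M-score and Welch-t p-values with
Benjamini-Hochberg adjustment and rank positions.

A synthetic-cohort generator (`seropanel.synthetic`) produces cohorts with
planted case-elevated features, subject-level biological noise, and
duplicate-spot technical noise calibrated to realistic replicate
reproducibility (log-data Pearson r ≈ 0.98, per-spot CV ≈ 9–11%), plus
on-disk GAL/GPR fixtures.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion; the two 100-subrun criteria take a few minutes each on one CPU.
Two clauses are expected to fail and are left failing deliberately: the
planted-marker-recovery count (the engine's smallest-set rule returns 2–4
features per subrun on the highly separable default cohort, so too few
features reach the 10% frequency threshold) and the null-control frequency
cap (chance best-of-9,480 associations on a fixed permuted labeling are
stably rediscovered by every subrun). Both assertions carry inline notes.

## CLI

```sh
# generate a synthetic fixture (40 GPRs + GAL + sample sheet + manifest)
seropanel simulate --out fixture/ --seed 42

# full pipeline: read -> preprocess -> 100 subruns -> panel -> verify -> NSC
seropanel run --gal fixture/layout.gal --gpr-dir fixture/ \
    --sample-sheet fixture/samples.tsv --out results/ --seed 42

# human-readable summary of a completed run
seropanel report --results results/
```

`run` writes `subruns.tsv`, `frequency.tsv`, `panel.txt`,
`panel_report.tsv`, `verification.tsv`, `intensity_matrix.tsv`, and a
`manifest.yaml` capturing every parameter and seed; identical manifests
reproduce byte-identical outputs.

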