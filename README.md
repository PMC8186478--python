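# cycleclass

Cell-cycle phase classification for single-cell RNA-seq, built around a
quiescent-state-aware phase vocabulary: **Neural G0, G1, Late G1, S,
S/G2, G2/M, M/Early G1**, plus a low-RNA outgroup class (**G1/other**)
and an explicit **Unknown** label for cells the classifier declines to
call. It is aimed at researchers studying quiescence and proliferation
in neural stem/progenitor cells and gliomas, where distinguishing a
transcriptionally active G0-like state from ordinary G1 matters both
biologically (stem-cell reservoirs) and clinically (tumor prognosis).

## What it does

* **Classifier with rejection.** Train any of four back-ends on a
  labeled reference — linear SVM with probability calibration
  (`SVMrej`), random forest (`RF`), PCA-space k-nearest neighbours
  (`KNN`), or a fully connected neural network with 100/50/25 hidden
  units and softmax output (`NN`). Features are the top 1,536 most
  variable genes of the log-normalized reference, standardized with
  stored training means/SDs. At prediction time a cell is labeled
  `argmax_c p(c | x)` if `max_c p(c | x) ≥ θ` (default θ = 0.7 for
  `SVMrej`) and `Unknown` otherwise. Query datasets may be from another
  species (two-column homology mapping) and may be missing genes:
  absent features contribute their training mean (z = 0), which keeps
  linear scores unbiased.
* **Validation tooling.** Monte-Carlo cross-validation (100 random
  holdouts of 1,000 cells by default) reporting per-class F1 and error
  rates, plus a sensitivity analysis that deletes a growing random
  fraction of the feature genes and re-runs CV.
* **Phase topology.** Each phase is summarized by its medoid (per-gene
  mean expression); pairwise Canberra distances
  `d(x, y) = Σᵢ |xᵢ − yᵢ| / (|xᵢ| + |yᵢ|)` (0/0 terms ≡ 0) thresholded
  at a cutoff — or at the smallest cutoff reaching a target mean degree
  (default 2.0, the degree of a closed cycle) — give an undirected
  network that recovers cell-cycle progression.
* **Marker discovery.** One-vs-rest Welch t-tests with
  Benjamini–Hochberg correction; a gene is a marker at
  avg logFC ≥ 0.3 (natural log) and adjusted p ≤ 0.05. Consensus
  signatures are the intersection of marker tables across datasets.
* **Tumor application.** Exclusion of non-neoplastic clusters via a
  lineage marker panel (MBP/PLP1, ETNPPL, RBFOX3, AIF1/CD14/CX3CR1/
  PTPRC); presence-logic stem-like-cell calling on raw counts
  (`(FUT4>0 ∨ L1CAM>0 ∨ PROM1>0) ∧ SOX2>0 ∧ TLR4=0`); hypergeometric
  overlap enrichment with representation factors.
* **Survival association.** A signature **eigengene** — the
  sign-corrected first principal component of the z-scored signature
  submatrix, unit variance — entered into a Cox proportional-hazards
  model with clinical covariates, and a top-vs-bottom-quartile
  Kaplan–Meier contrast tested with the Fleming–Harrington G-ρ
  weighted log-rank statistic (weights S(t⁻)^ρ; ρ = 0 is the plain
  log-rank test).
* **Synthetic data.** A negative-binomial simulator of a cycling
  population with planted phase markers, cyclic marker sharing between
  adjacent phases, log-normal library sizes and a low-depth outgroup —
  and a survival-cohort simulator with a latent signature factor —
  provide ground truth for every stage.

## Worked example

```python
import numpy as np
from cycleclass import (SimulationConfig, simulate_cycle_counts,
                        normalize_log, select_hvg, cross_validate)

sim = simulate_cycle_counts(SimulationConfig(seed=1))   # 5,000 genes x 3,000 cells
norm = normalize_log(sim.counts)                        # per-cell 10k + ln(1+x)
features = select_hvg(norm, 1536)
report = cross_validate(norm, sim.true_labels, method="NN",
                        n_iter=2, holdout_size=1000, seed=1,
                        feature_genes=features)
print(f"mean error {report.mean_error:.4f}, "
      f"macro-F1 {report.f1['f1'].mean():.4f}")
```

prints

```
mean error 0.0025, macro-F1 0.9906
```

i.e. on held-out simulated cells the network misassigns ~0.3% of cells
and averages an F1 of 0.99 across the eight classes — the simulation at
default effect size (1.5 log2 fold-change on 100 markers per phase) is
largely but not perfectly separable, with residual confusion between
cyclically adjacent phases and the low-RNA outgroup.

On the survival side (same pipeline as `scripts/acceptance.py`, seed 1):

```
eigengene vs latent factor: r = 0.994
   term      coef       se            p
  score -0.465437 0.055770 7.083867e-17
quartile KM medians: top 1181 days, bottom 350 days; G-rho p = 2.34e-11
```

The eigengene reconstructs the simulated latent signature factor
(r = 0.99), the Cox coefficient recovers the simulated protective
log-hazard (truth −0.5) within one standard error, and the top
eigengene quartile lives substantially longer than the bottom quartile.

## Command line

```bash
cycleclass simulate cycle --seed 0 --out data/
cycleclass train --matrix data/ --labels data/labels.tsv --method NN --out model.pkl
cycleclass predict --matrix query/ --model model.pkl --cutoff 0.7 --out calls.csv
cycleclass cv --matrix data/ --labels data/labels.tsv --iters 100 --holdout 1000 --out cv/
cycleclass sensitivity --matrix data/ --labels data/labels.tsv --grid 0,0.2,0.4 --out sens/
cycleclass markers|network|tumor-filter|stemlike|enrich|eigengene|survival ...
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the whole toolkit from scratch on freshly simulated data:
default-scale simulation, NN cross-validation, gene-removal
sensitivity sweep, marker recovery against planted truth, the medoid
network at target degree 2, stem-like-cell logic with overlap
enrichment, and the eigengene/Cox/Kaplan–Meier survival analysis. It
prints a per-stage summary and writes the results JSON to `--out`.
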