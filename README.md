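# telostorm

Telomere shape analysis for 3D STORM localization microscopy, plus the
companion assays used to characterize engineered telomere chromatin: nuclear
foci colocalization scoring, telomere restriction fragment (TRF)
densitometry, and ChIP dot-blot normalization. A seeded synthetic-data
generator produces every input with known ground truth, so the whole
pipeline can be exercised and validated without external datasets.

## The problem

Telomeres are smaller than the diffraction limit; under single-molecule
localization microscopy (STORM) each telomere appears as a cluster of
hundreds of localizations. Experiments that manipulate telomere
chromatin — for example tethering the heterochromatin protein HP1α to
telomeres through a TRF1 fusion — change telomere *shape*, and the analysis
task is to quantify that change robustly across groups of cells.

The core statistic is the radius of gyration of each telomere cluster,

$$R_g^2 = \frac{1}{N}\sum_{k=1}^{N}\left(\vec r_k - \vec r_{\mathrm{com}}\right)^2,$$

the RMS distance of the $N$ localization points from their center of mass.
The pipeline: drift-correct the molecule list by image correlation, find
clusters (DBSCAN), keep clusters with **more than 200 localizations** whose
center of mass lies near the focal plane, compute per-telomere $R_g$, and
summarize per group — including the fraction of "irregular" telomeres with
$R_g$ **at or above** a cutoff recomputed as the reference group's mean
$R_g$. Groups are compared with ANOVA + Tukey HSD (all pairs) or
ANOVA + Dunnett (vs control), and two-tailed unpaired t tests, with s.e.m.
error bars.

Alongside: %EGFP area per nucleus and % telomeres colocalized with a
partner channel; %TIF (telomere dysfunction-induced foci, telomere foci
overlapping 53BP1 damage foci) per nucleus under an identical-threshold
policy; TRF mean fragment length $\sum \mathrm{Int}_i / \sum
(\mathrm{Int}_i/\mathrm{MW}_i)$ from gel densitometry with log-linear ladder
calibration; and ChIP dot-blot ratios to a 10% input with per-H3
renormalization and pooled-control fold changes.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

Simulate a two-arm experiment (a reference arm targeting an observed mean
Rg of 84 nm and an enlarged arm at 90.7 nm, ~70 telomeres each), run the
full pipeline, and compare the arms:

```python
from telostorm.pipeline import validate_config, run_shape_experiment

cfg = validate_config("""
seed: 42
acquisition: {n_frames: 5000}
analysis: {reference_group: TRF1}
groups:
  - label: TRF1
    n_nuclei: 4
    telomeres_per_nucleus: 18
    structure: {target_rg_nm: 84.0, size_cv: 0.25}
  - label: TRF1HP1a
    n_nuclei: 4
    telomeres_per_nucleus: 18
    structure: {target_rg_nm: 90.7, size_cv: 0.25}
""")
report, table = run_shape_experiment(cfg)
print(f"cutoff (TRF1 mean Rg): {report.cutoff_nm:.1f} nm")
for row in report.group_summary:
    frac = report.fractions_irregular[row["group"]]
    print(f"{row['group']:>10s}: n={row['n']:3d}  mean Rg {row['mean_rg_nm']:.1f} nm "
          f"(sem {row['sem_nm']:.1f})  irregular fraction {frac:.2f}")
for comp in report.comparisons:
    print(f"{comp['comparison']}: p_adj = {comp['p_adj']:.4f}")
```

Output:

```
cutoff (TRF1 mean Rg): 84.5 nm
      TRF1: n= 70  mean Rg 84.5 nm (sem 1.5)  irregular fraction 0.47
  TRF1HP1a: n= 71  mean Rg 90.0 nm (sem 2.0)  irregular fraction 0.59
TRF1 vs TRF1HP1a: p_adj = 0.0255
```

Reading the numbers: each simulated telomere was clustered from its
localizations and filtered (>200 localizations, near the focal plane); the
reference arm's realized mean Rg (84.5 nm) becomes the irregularity cutoff;
the enlarged arm has a higher mean Rg and a larger fraction of telomeres at
or above the cutoff, and Tukey's HSD flags the difference at p < 0.05.
`report.stage_counts` records how many localizations and clusters each
filter stage retained, and the resolved config and seed are embedded for
provenance; re-running the same config + seed reproduces the report
byte-for-byte.

The same workflow is available from the shell:

```sh
telostorm run-experiment --config experiment.yml --seed 42 --out-dir runs/demo
telostorm rg-pipeline --molecules molecules.csv --group TRF1 --out runs/nucleus0
telostorm coloc --chan-a tel.tif --chan-b 53bp1.tif --mask nucleus.tif \
    --threshold-a 300 --threshold-b 300 --out coloc.csv
telostorm trf --lane lane.csv --ladder ladder.csv --out trf.csv
telostorm dotblot --grid chip.csv --control Vonly --out folds.csv
```

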