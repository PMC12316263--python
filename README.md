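# scanqc

Team-scale **visual quality control** for the outputs of neuroimaging
processing pipelines on large databases.

When a lab runs a dozen pipelines (tensor fitting, parcellation,
tractography, skull-stripping, ...) over thousands of MRI sessions,
quantitative outlier detection alone misses many algorithm failures — every
output has to be *looked at*, quickly and consistently, by a team. `scanqc`
provides the machinery for that:

- **Triage** of raw data before processing: diffusion scans (DWI) without
  their bval/bvec gradient-table sidecars are ignored, as are DWI with fewer
  than 6 volumes unless they are reverse phase-encoding scans accompanying a
  more highly sampled DWI; every exclusion is logged with a machine-readable
  rule code.
- **Deterministic QC PNGs**: each pipeline output is condensed into a single
  lossless PNG — tri-planar (axial/coronal/sagittal) slice grids, label-map
  overlays on T1w or FA backdrops, side-by-side before/after comparisons,
  axial rows of scalar maps with colorbars, and multipage QC documents
  flattened into one image. Rendering is a pure function of its inputs:
  re-running produces byte-identical files.
- **Auto-failure**: a pipeline run that did not produce all of its expected
  outputs (its own QC document included) is automatically recorded as a QC
  failure, no human review needed.
- **Three-state review**: a reviewer cycles through a pipeline's PNGs
  (manually or in timed montage mode) and records **yes** (ran properly) /
  **maybe** (believable but not visually good; the downstream analyst
  decides) / **no** (failed), with an optional free-text reason. All rows
  start as *yes*, so only problems cost effort. Every verdict is pushed to a
  CSV audit table immediately and atomically.
- **Aggregation**: audit CSVs share one schema
  (`dataset,pipeline,subject,session,acquisition,run,item,qc_status,user,timestamp,reason`)
  and merge across datasets and pipelines with last-write-wins conflict
  resolution.
- **Agreement statistics**: Fleiss' kappa across raters with Landis–Koch
  banding, and 2×2 confusion matrices against an automated pass/fail
  classifier's label CSV.

Fleiss' kappa for an N×k rating-count matrix with n raters per item:

    P_i   = (Σ_j n_ij² − n) / (n(n−1))        p_j = Σ_i n_ij / (Nn)
    P̄     = mean_i P_i                        P̄_e = Σ_j p_j²
    κ     = (P̄ − P̄_e) / (1 − P̄_e)

Everything is testable without access-restricted data: a fixture module
generates phantom T1w volumes, 4D DWI stand-ins with sidecars, parcellation
label maps, BIDS-organized directory trees with controllable per-run
completeness, and simulated multi-rater panels with a tunable agreement
level.

## Worked example

```python
import numpy as np
from scanqc import RatingPanel, fleiss_kappa, confusion

# two items, four raters: split 2/2 on the first, unanimous on the second
panel = RatingPanel(np.array([[2, 2, 0], [0, 4, 0]]))
res = fleiss_kappa(panel)
print(f"kappa={res.kappa:.3f} p_bar={res.p_bar:.3f} p_e={res.p_e:.3f} band={res.band}")

# human vs automated classifier over 1560 scans
human   = ["pass"] * 1558 + ["reject"] * 2
machine = ["pass"] * 1554 + ["reject"] * 4 + ["pass", "reject"]
cm = confusion(human, machine)
print(f"cells=({cm.a},{cm.b},{cm.c},{cm.d}) rows={cm.row_totals} "
      f"cols={cm.col_totals} total={cm.total} agree={cm.percent_agreement:.2f}%")
```

prints

```
kappa=0.111 p_bar=0.667 p_e=0.625 band=slight or worse
cells=(1554,4,1,1) rows=(1558, 2) cols=(1555, 5) total=1560 agree=99.68%
```

The first line: observed agreement (0.667) barely exceeds chance (0.625), so
the chance-corrected kappa is low even though most votes coincide. The
second: the two methods disagree on only 5 of 1560 scans.

The shell workflow, end to end on synthetic data:

```sh
scanqc fixtures --out demo --subjects 3          # phantom BIDS tree
scanqc triage --config config.yaml --dataset demo --out triage.csv
scanqc generate --config config.yaml --dataset demo --pipeline tensor
scanqc review --config config.yaml --dataset demo --pipeline tensor --user alice
scanqc aggregate --config config.yaml --out all_qc.csv
```

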