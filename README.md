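# vmatqa

Aperture complexity scoring for VMAT treatment plans, with reference-cohort
comparison and ROC-based calibration of a pass/fail review threshold for
patient-specific QA.

The plan metric is the MU-weighted mean over all control-point apertures of
`y/A` — the aperture's side perimeter `y` (mm; boundary edges parallel to
the leaf travel direction, i.e. excluding leaf-end faces) divided by its
open area `A` (mm²) — giving a complexity in mm⁻¹ that is independent of
plan dose and only weakly sensitive to target size. Plans with highly
irregular, jagged MLC apertures score high and are disproportionately likely
to fail pretreatment measurement QA; the tool flags them for reoptimization
before they move further through the planning workflow.

## What's in the box

| module | role |
| --- | --- |
| `vmatqa.mlc` | aperture geometry: open area, side perimeter, per-aperture `y/A`, pixel-rasterization oracle |
| `vmatqa.rtplan` | DICOM RTPLAN reader, plan/arc/control-point model, MU allocation from cumulative meterset weights |
| `vmatqa.metric` | per-arc and per-plan MU-weighted complexity, gantry-angle profile, CSV/JSON export |
| `vmatqa.cohort` | reference-cohort CSV I/O, per-site summary tables, histogram, percentile |
| `vmatqa.roc` | confusion counts, empirical ROC curve and AUC, constrained threshold recommendation |
| `vmatqa.synth` | seeded synthetic RTPLAN and labeled-cohort generators for testing and calibration |
| `vmatqa.cli` | `vmatqa` command-line front end |

A small self-contained DICOM codec (`vmatqa._dicom`, Explicit/Implicit VR
Little Endian, RT Plan subset) backs the reader and writer, so the package
has no DICOM dependency.

## CLI

```sh
# score a plan; exit 0 = ok, 3 = flagged for review, 1 = error
vmatqa analyze plan.dcm --threshold 0.18 --cohort cohort.csv --cp-csv cps.csv

# summarize a scored cohort at a threshold (per-site counts and moments)
vmatqa cohort-stats cohort.csv --threshold 0.18

# ROC analysis + threshold recommendation at a false-positive-rate cap
vmatqa roc cohort.csv --max-fpr 0.10 --out-csv roc.csv

# synthetic fixtures (seeded, deterministic)
vmatqa simulate rectangle rect.dcm --width 100 --n-bands 10
vmatqa simulate modulated mod.dcm --radius 8 --sigma 4 --seed 7
vmatqa simulate cohort cohort.csv --n-pass 649 --n-fail 62
```

The default review threshold of 0.18 mm⁻¹ is an institution-specific
calibration value, not a universal constant: it depends on the machine, the
dose algorithm and the QA criteria in use. Recalibrate against your own
cohort with `vmatqa roc` before gating a clinical workflow on it.

Cohort CSV format: header
`plan_id,site,fractionation,complexity_mm_inv,qa_pass` with
`fractionation` in `{standard, SBRT, unknown}` and `qa_pass` in
`{true, false, blank}` (blank = outcome unknown).

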