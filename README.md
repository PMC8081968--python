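# neuroqc

Automated sanity checks, segmentation snapshots, project-wide result
aggregation and assisted visual review for filesystem-backed neuroimaging
projects.

## The problem

Cohort imaging studies accumulate thousands of MR and PET sessions, each
taken through processing pipelines (tissue segmentation, subcortical and
hippocampal-subfield parcellation, diffusion fits, registrations). Every
acquisition and every pipeline run can silently go wrong — a mistyped
subject identifier, a tracer dose entered in the wrong unit, a scan
acquired on the wrong scanner, a segmentation missing a structure — and
errors that slip through propagate into analyses. Visual inspection alone
does not scale; fully automatic image-quality metrics do not generalize
across modalities and pipelines. `neuroqc` takes the middle road: every
step is punctuated with small, documented, *self-testing* checkpoints, and
the remaining visual review is made cheap by pre-rendered snapshots and a
collaborative rating gallery.

It is intended for imaging-platform engineers and QC raters at research
centers that manage their own scanner data on disk (or on any platform
they can mirror to disk).

## Core concepts

- A **Test** is one checkpoint over a session or scan. It carries a
  human-readable docstring (its specification), returns a binary
  `has_passed` plus a `data` detail list, and — crucially — declares two
  fixture sessions, one on which it must pass and one on which it must
  fail. Re-running every test against its fixture pair (`self_check`)
  turns the whole registry into its own regression suite.
- A **Validator** is an ordered list of Tests run over one session. All
  tests always run (a report is a complete checklist); the outcome is
  persisted next to the data as JSON, Markdown and PDF, and failing
  scan-level tests can downgrade per-scan quality flags
  (usable → questionable → unusable).
- The shipped **PetSessionValidator** runs nine checks on every PET
  session, in order: tracer registered and allowed; metadata consistent
  across scans; scanner model correct; subject weight within
  [40, 150] kg; injected dose within [1.5e8, 3.5e8] Bq; subject-id
  format; usable T1-weighted image available; Centiloid runnable; FDG
  quantification runnable. Sibling validators cover MR archiving and the
  outputs of ASHS, SPM12, FreeSurfer 6, FSL DTIFIT and ANTs (file
  manifests, software versions, execution time, label completeness,
  volume safety intervals, snapshot generation).
- **Snapshots** are deterministic raster grids of segmentation slices
  overlaid on anatomy (solid color or contours, static PNG or fading
  GIF), rendered offscreen by `neuroqc.snapshot.plot_segment`.
- **Collection** turns a whole project into spreadsheets: all FreeSurfer
  `aseg.stats` volumes in one table, all validator outcomes in a
  pass/fail matrix, all snapshots in one folder with a manifest.
- **Review** serves the snapshot folder as a minimal web gallery where
  raters assign scores (0 fail / 1 doubtful / 2 pass) and comments to an
  append-only TSV log, with navigation that jumps from one failed
  checkpoint to the next.
- The **fixtures** module generates complete synthetic projects — NIfTI
  phantoms, label maps with exact voxel counts, JSON metadata sidecars,
  genuine-dialect `aseg.stats` tables — with controllable single-defect
  injections. These fixtures are what the self-check harness runs on.

## Worked example

```sh
$ neuroqc fixtures make-project demo --sessions 3 --seed 4
$ neuroqc run PetSessionValidator demo/ALFA00001/ALFA00001_PET01 --project demo
PASS  IsTracerCorrect
PASS  IsSeriesDescriptionConsistent
PASS  IsScannerVersionCorrect
PASS  IsSubjectWeightConsistent
PASS  IsTracerDoseConsistent
PASS  IsSubjectIdCorrect
PASS  HasUsableT1
PASS  IsCentiloidRunnable
PASS  IsFDGQuantificationRunnable
9 passed, 0 failed
```

The synthetic PET session is clean, so all nine checks pass; the full
report (JSON + Markdown + PDF, each section quoting the test's docstring)
is stored under
`demo/ALFA00001/ALFA00001_PET01/resources/PetSessionValidator/`.
Collecting all FreeSurfer volumes of the project into one spreadsheet:

```sh
$ neuroqc collect freesurfer6 aseg demo --out aseg.csv
3 rows -> aseg.csv
$ head -2 aseg.csv
session_id,Brain-Stem,Left-Amygdala,Left-Hippocampus,Left-Lateral-Ventricle,Right-Amygdala,Right-Hippocampus
ALFA00001_MR01,23341.3,1585.0,4249.4,6942.9,1691.8,4468.9
```

One row per session with a parseable `aseg.stats`, one column per
structure, cells in mm³ verbatim from the table. And the registry's own
health check:

```sh
$ neuroqc self-check --seed 2
...
30/30 tests self-check clean
```

meaning every shipped test passed on its passing fixture and failed on
its failing fixture.

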