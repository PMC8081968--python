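# Methods

## The validation model

`neuroqc` models quality control as ordered lists of binary checkpoints
(*Tests*) grouped into *Validators*, run over sessions of a
filesystem-backed imaging project. Three design commitments shape the
engine:

1. **Completeness over short-circuiting.** A validator always runs every
   test, regardless of earlier failures, so a report is a complete
   checklist of the session's state. Downstream gating (e.g. skipping a
   pipeline when archiving checks fail) is left to the caller, which
   reads the report summary.
2. **Failure isolation.** An exception inside a test is converted into a
   failing result carrying the error description; it never aborts the
   validator. This keeps a single malformed file from hiding the status
   of every other checkpoint.
3. **Self-testing by fixtures.** Every test declares one fixture session
   on which it must pass and one on which it must fail. `self_check`
   re-executes the whole registry against these pairs; on a correct
   build every row reads (pass-on-passing, fail-on-failing) = (true,
   true). Because all tests share one template, this harness needs no
   updating when tests are added — adding the two fixtures *is* the
   test's test. `self_check` runs with quality-flag persistence disabled
   so fixtures are never mutated and the check is a fixed point.

Reports serialize to a normative JSON schema
(`{validator, session_id, subject_id, generated, code_sha, tests:[{id,
docstring, has_passed, data}], summary:{passed, failed}}`), to Markdown
(one section per test quoting the docstring verbatim, so the report is
self-documenting), and to PDF. The PDF is a paginated text rendering of
the Markdown produced with matplotlib's PDF backend; the Markdown and
JSON files are the primary artifacts and the PDF is a portable
convenience. `code_sha` is read from a `BUILD_SHA` file shipped next to
the package when present, else "unknown", so reports remain reproducible
outside a checkout.

## The data model

The on-disk layout mirrors the Project → Subject → Session →
Scan/Resource hierarchy of imaging databases:
`<root>/<subject>/<session>/scans/<scan>/{image.nii.gz, image.json}` and
`<root>/<subject>/<session>/resources/<NAME>/...`. Metadata sidecars are
JSON with DICOM-derived keys (BIDS-style naming); this avoids a DICOM
parser dependency while preserving every checked field, and a DICOM
ingestion adapter is a natural extension point. Scans are ordered
lexicographically by id so reports are deterministic. Quality flags
persist per scan in `quality.json`; engine-initiated transitions are
downgrade-only (usable → questionable → unusable), manual upgrades
require an explicit force. PET and MR visits of one subject are sibling
sessions under the subject directory, which is how the PET validator's
T1 lookup finds the anatomical reference.

## Shipped checks and their parameters

All thresholds live in one `CheckConfig` (overridable from a JSON file):

- tracers allowed: {FDG, FLUTEMETAMOL}; PET scanner
  "SIEMENS Biograph64 VG51C"; MR scanner "Philips Ingenia CX". String
  comparisons trim whitespace and ignore case; raw values are echoed in
  the failure payload.
- subject weight in [40, 150] kg and injected dose in
  [1.5e8, 3.5e8] Bq. Both intervals are closed: a physical reading
  exactly at a bound is acceptable.
- subject-id pattern `^[A-Z]+[0-9]{5}$` (configurable; a letters+5-digits
  accession-number convention).
- consistency keys checked across scans of one session: PatientID,
  StudyDate, Manufacturer, ManufacturerModelName. A single-scan session
  is vacuously consistent.
- T1 designation: any SeriesDescription containing "T1"
  (case-insensitive) with quality flag `usable`.
- per-pipeline derivative expectations (file-manifest globs, exact
  software-version strings, an execution-time ceiling of 3600 s for the
  SPM12 segmentation, label sets and volume safety intervals in mm³).
  The shipped intervals are deliberately broad, literature-plausible
  placeholders and must be **site-calibrated**; they are not published
  reference ranges.

Two decisions where the design space was genuinely open:

- **Runnability under tracer mismatch.** `IsCentiloidRunnable` on an FDG
  session (and vice versa) returns pass-with-note "not applicable"
  rather than failing: a clean session should be all-green, and tracer
  registration problems are already the tracer check's job. A missing
  tracer therefore fails only `IsTracerCorrect`.
- **Manifest extras.** Unexpected extra files are reported but do not
  fail `HasCorrectItems`, because pipelines add logs freely; only
  missing expected entries fail.

Validator membership beyond the PET session validator (whose nine tests
and order are fixed) is a shipped-default composition: ArchivingValidator
(MR) = NIfTI conversion (scan-level, downgrading failing scans to
questionable), subject id, MR scanner, consistency; ASHSValidator =
subfield completeness, version, manifest, subfield-volume intervals,
snapshot; SPM12Validator = tissue-volume intervals, execution time,
manifest, version, snapshot; FreeSurfer6Validator = manifest, version,
snapshot; DTIFIT/ANTS = manifest, version. DTIFIT and ANTs ship no
snapshot test because their outputs are scalar maps rather than label
images and the snapshot renderer draws label overlays.

## Volumes

`compute_label_volumes` counts voxels per integer label and multiplies
by the voxel volume from the header zooms (anisotropic voxels supported;
no affine resampling; background label 0 excluded; non-integer data is
an error). It is exact by construction and is verified against an
independent triple-loop counter. `parse_aseg_stats` reads the FreeSurfer
`aseg.stats` dialect: `#` comment header, a `# ColHeaders` line naming
the columns, whitespace-delimited rows; it returns StructName →
Volume_mm3 verbatim and falls back to the standard column order for
stripped files. A region that has a configured safety interval but no
measured volume fails the interval check (an unmeasured structure is not
evidence of normality).

## Snapshots

Volumes are reoriented to RAS on load, so array axes 0/1/2 are
sagittal/coronal/axial. Slice selection takes the bounding range of
nonzero segmentation along the plane axis, keeps slices with at least
`min_voxels` foreground voxels, and picks `n` evenly spaced interior
positions (`n=1` gives the support midpoint); an all-zero segmentation
is an error. The background is windowed to its 1st–99th intensity
percentiles (deterministic, robust to outliers) and rendered grayscale;
labels are alpha-blended at the requested opacity, either solid or as
1-pixel contours (pixels whose in-slice 4-neighborhood contains a
different label; the field-of-view border counts as different). Colors
come from a fixed categorical palette keyed by sorted label value so a
given label keeps its color across sessions; an explicit colormap
overrides per label. Background and segmentation must share the voxel
grid — mismatches are an error, never silently resampled. Animation
ramps the overlay opacity linearly 0 → peak → 0 over a configurable
frame count (default 11, odd so the middle frame equals the static
render). Identical inputs give byte-identical PNGs.

## Collection and review

Aggregation reads only persisted artifacts: `aggregate_aseg` parses each
session's own `aseg.stats`; `aggregate_tests` reads report JSONs and
orders columns by validator declaration. Rows are the sessions a
validator applies to (PET sessions for the PET validator, MR for
archiving, resource-bearing sessions for derivative validators);
applicable sessions without a report get an empty row plus a note.
Snapshot collection copies every image referenced by report payloads
into one flat folder under `<subject>_<session>_<test>` names and writes
a manifest joining each snapshot to its per-test outcomes.

The review store is an append-only TSV log (snapshot, rater, score,
comment, timestamp) with per-append file locking; the "current" view —
latest record per (snapshot, rater) — is derived, never stored, so
history is always preserved. The score scale defaults to 0–2
(fail/doubtful/pass) and is configurable. `next_failed` scans forward
from the current index with wrap-around for the next snapshot failing a
chosen checkpoint. The web layer is a deliberately minimal single-page
gallery on the standard-library HTTP server; every behavior
(storage, navigation, export) lives in plain functions testable without
a browser.

## Synthetic data

The generator emulates the *structure* of a cohort imaging project, not
its image content: ellipsoidal two-shell phantoms with seeded Gaussian
noise stand in for anatomy (1 mm isotropic, 16³ by default), and label
maps are grown as connected blobs with *exact* requested voxel counts
(24³ by default), so volume recovery is testable to equality. Metadata
defaults define the clean study conditions: weight 75 kg, dose 2.0e8 Bq,
FDG tracer, the expected PET/MR scanner strings, well-formed subject
ids. `aseg.stats` fixtures are written in the genuine FreeSurfer dialect
with per-structure volumes jittered ±10% around literature-scale means;
they are intentionally independent of the toy aseg label map, since the
parser and the aggregator — not FreeSurfer itself — are under test.
Each registered defect (out-of-range weight/dose, wrong scanner, missing
tracer, malformed id, inconsistent metadata, missing NIfTI, unusable T1,
missing subfield, missing manifest file, wrong version, overlong
execution, abnormal or empty label map) maps to one targeted test plus
the closure of tests whose preconditions it necessarily breaks (e.g. an
empty label map fails completeness, volume-interval and snapshot checks
together; an unusable T1 also blocks the applicable quantification
pipeline). Everything derives deterministically from one seed, with
per-session seeds derived from it.

Passing tests on these fixtures demonstrates the checking, reporting,
aggregation and navigation machinery — not the clinical validity of any
threshold on real scanner data: the phantoms have no real anatomy, PET
kinetics, or scanner artifacts, and the shipped safety intervals are
placeholders until site-calibrated.

## Problem sizes and numerical choices

The test suite and the acceptance script use small, fixed problem sizes
chosen to exercise every code path exactly: 16³ phantoms and 24³ label
maps, a self-check project of ~30 fixture subjects, a 10-session
aggregation project with 3 planned defective sessions, 100 random label
maps for the volume oracle, and 1,000 random galleries for the
navigation oracle. All randomness flows through
`numpy.random.default_rng` seeds; gzip writing is deterministic, so
whole fixture trees checksum identically per seed. Volume comparisons
are exact (integer voxel counts times exact float products); interval
endpoints are inclusive; timestamps are fixed where byte-stable outputs
matter.

## Known limitations

- No DICOM ingestion; metadata arrive as JSON sidecars.
- No remote database backend; the adapter surface is the filesystem
  layout (a REST-backed loader could implement the same model API).
- Derivative validator membership and all safety intervals are shipped
  defaults, not validated reference configurations.
- The review web app has no authentication beyond the rater-name field
  and is meant for trusted internal networks.
- Image-content quality metrics (SNR, motion, prediction-based QC) are
  out of scope; checks operate on metadata, files, labels and volumes.
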