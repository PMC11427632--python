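# Methods

## The monitoring problem

A longitudinal multicenter fMRI study lives or dies by the temporal
stability of its scanners.  Because human data confound scanner state
with subject state, stability is tracked with a physical phantom — an
agar-filled plastic cylinder (235 mm long, 111 mm diameter; agar rather
than water for brain-like relaxation behaviour and fast settling) —
scanned with the study's own T2\*-weighted EPI sequence after subject
sessions.  Each phantom series is reduced to a metric vector; the dated
sequence of vectors per scanner is the object the monitoring layer
analyses.  No consortium data ships with this package: every input is
produced by the simulator, which is first-class, tested code.

## Signal model of the simulator

The simulator is signal-statistical, not physical.  A session is

S(x, t) = A·m(x)·(1 + d₁τ + d₂τ²) + g·A·m_g(x) + ε(x, t)

* `m` — binary cylinder mask by voxel-centre test.  The volume centre
  is the voxel ⌊(n−1)/2⌋ per axis; no rim anti-aliasing, because all
  metrics use interior ROIs that never touch the rim.
* `m_g` — `m` cyclically shifted by half the matrix along the
  phase-encode axis (default y): the N/2 EPI ghost as a minimal
  generative counterpart.  `g` is the ghost amplitude as a fraction of
  the in-phantom signal `A`.
* τ = (t − n_dummy)/(T − n_dummy − 1) runs 0→1 over the retained
  volumes, so `d₁` is *exactly* the fractional drift the drift
  estimator sees.  The n_dummy (default 5) leading volumes are
  simulated on the extrapolated line (τ < 0), not skipped, so the
  pipeline's discard step is exercised.
* ε — i.i.d. Gaussian noise of SD σ.  Thermal noise only: no
  physiological noise, B0 inhomogeneity, k-space effects or multi-coil
  reconstruction.  Background noise is therefore zero-mean Gaussian,
  not Rayleigh (see SNR below).
* Spikes are whole-volume multiplicative gains at listed time points.

Identical seeds give bit-identical arrays.  Monitoring histories draw
one sub-seed per session from a `SeedSequence`, share the baseline
parameters, and apply per-session anomaly overrides (e.g. `ghost_frac`
×10).

Default study conditions used throughout tests and the acceptance
script: A = 1000, σ = 10 (image SNR ≈ 100, a typical 3 T phantom
value), T = 100 volumes for single-session estimation and T = 30 for
monitoring histories, weekly cadence.  The analysis grids (48³-scale,
4–5 mm voxels, ~220–240 mm FOV) keep a simulated session in tens of
milliseconds while leaving the phantom and its half-FOV ghost
non-overlapping; results are intensity-scale- and grid-scale-free
because every metric is a ratio.

## Metric estimators

The study protocol this package implements lists its metrics but defers
their formulas to a companion methods publication; the definitions here
follow the fBIRN lineage of phantom stability analysis and are fixed
contracts of this package:

* **SNR** — mean of the temporal-mean image over the signal ROI,
  divided by the background SD of the temporal-mean image corrected by
  the Rayleigh factor 0.655.  The factor is part of the protocol
  definition (magnitude-image background statistics); since the
  simulator's background is signed Gaussian, the closed-form
  expectation used as test oracle is SNR = 0.655·A·√T′/σ.
* **SFNR** — per-voxel temporal mean over residual SD after removing a
  2nd-order polynomial trend (residual SD uses n−3 degrees of freedom),
  averaged over the signal ROI.  Expectation A/σ.
* **PSC** — 100 · SD of the 2nd-order-detrended ROI-mean time course /
  its mean.  Expectation 100·(σ/√V)/A for a V-voxel ROI.
* **PSG** — 100 · (ghost-ROI mean − background mean) / signal-ROI mean
  on the temporal-mean image.  Background correction makes noise-free
  ghost-free data read exactly 0 and allows small negative values.
* **drift** — endpoint difference of the 1st-order least-squares fit to
  the ROI-mean time course, divided by the time-course mean, ×100.
  Detrending is order 2 for the fluctuation metrics but drift is the
  order-1 endpoint difference, keeping the two orthogonal: adding pure
  linear drift changes PSC/SFNR-fluctuation by nothing.  Note the mean
  of a 1 + d·τ ramp is 1 + d/2, so the noise-free drift estimate is
  100·d/(1 + d/2) — for d = 1.5% that is 1.489, a bias far below the
  ±0.2 pp recovery tolerance; the unit tests assert the exact value.
* **placement** — Euclidean distance between the detected object's
  centre of mass and the volume-centre voxel, in mm; flagged beyond a
  10 mm threshold (order of a phantom-radius fraction that visibly
  perturbs metrics; configurable).

ROIs: the object is the largest connected component above half the
99.5th intensity percentile of the mean image (≥ 1% FOV coverage,
otherwise a detection error).  The signal ROI is a cube (or square in
central-slice mode) of side half the object's in-plane
equivalent-disc diameter, centred on the centre of mass and clipped to
the object support; the ghost ROI is the signal ROI shifted by half the
matrix along the phase axis minus the object support (a mis-centred
phantom may overlap its own ghost, which is excluded rather than an
error); backgrounds are 8×8(×8) corner blocks outside both supports.
Default mode is `volume` — metrics over the full ROI volume rather than
a single slice, the more stable choice — with `central-slice` retained
for comparability with older single-slice pipelines.

## Longitudinal monitoring

Control limits are centre ± k·SD with k = 2.5 and the sample SD (n−1);
the yearly tables have small n, making the bias-corrected form the
defensible default.  A point exactly on a limit is *not* flagged
(strict inequality, fixed by convention).  Two modes:

* **global** (default) — centre/SD from all observations: the post-hoc
  analysis of a completed study, single pass, no iterative re-limiting.
* **rolling** — centre/SD from the trailing `n_window` = 20 (minimum
  10) observations *excluding* the evaluated point: the prospective
  early-warning variant.  Leave-current-out matters; a spike must not
  shield itself.

The two modes answer different questions, and the distinction is not
cosmetic: a *sustained* shift (e.g. ghosting up tenfold for the final
8 of 60 sessions) inflates the global SD it is judged against, landing
the shifted points near z ≈ 2.5 regardless of the shift's size — the
classic control-chart masking effect.  The rolling chart judges the
onset against clean trailing history and flags it decisively, which is
why the ghosting-fault scenario is run in rolling mode.

At k = 2.5 the two-sided Gaussian tail gives a 1.24% false-flag rate
per point — roughly one recheck per 80 sessions, the calibration the
acceptance script verifies on 10⁴ i.i.d. points.

A **single-metric alert** operationalizes the localized-fault
signature: ≥ 3 (configurable) consecutive sessions flagged on one
metric while no *other* metric shows a systematic change — its own
≥ 3-consecutive run — within the same span.  Isolated single-session
flags on other metrics do not veto an alert, since the limits produce
those at the tail rate by construction.

Yearly summaries report n, mean, SD and CV = SD/mean per calendar year
(acquisition-date year, no fiscal offsets); a year with one observation
yields an explicit "CV undefined" marker, an absent year a "missing"
marker, and a zero-mean year an undefined marker with reason.

## Human-data triage

The package computes no image-quality metrics for human data; it
ingests per-image JSON documents (MRIQC output dialect: top-level
numeric keys, one nesting level flattened with dotted names) and
screens them per metric with robust z-scores, z = (x − median)/
(1.4826·MAD), flagging |z| > 2.5.  Median/MAD rather than mean/SD so a
single bad subject cannot mask itself — deliberately different from
the phantom control limits, where the stream is assumed mostly clean.
Metrics with fewer than 3 observations or zero MAD are skipped with a
note.

Quality labels were expert judgments in the original protocol and are
inherently subjective; the rules here produce *suggestions* only
(poor ⟸ misplaced FOV ∨ incomplete session ∨ ≥ 2 flagged metrics;
intermediate ⟸ exactly 1; good otherwise), with "a bit of" vs
"strong" artifact thresholds explicitly package conventions.  The label
store is append-only; human overrides add rows and the latest row per
(session, modality) wins in the tally, so the audit trail is never
rewritten.

## What the synthetic tests do and do not show

Passing parameter recovery shows the estimators are unbiased and
correctly scaled *under the simulator's assumptions*: binary cylinder,
stationary Gaussian noise, ideal half-FOV ghost, polynomial drift.
Real phantom data add T2\* decay, ghost phase structure, spatial noise
correlation from parallel imaging, slow thermal trends that are not
polynomial, and vibration — so absolute metric values on real scanners
will differ, while the relative, longitudinal behaviour (what
monitoring consumes) is the faithful part.  The scenario tests
demonstrate *detectability* of faults of stated sizes, not field
sensitivity/specificity of any particular scanner model.

## Numerical and interface choices

* NIfTI-1 only; NIfTI-2 rejected with a clear message.  3-D images are
  promoted to t = 1.  Loaders reject non-finite voxels, naming the count.
* The session-name convention
  `sub-<id>_ses-<YYYYMMDD>_site-<code>[_entities]_<suffix>.nii[.gz]` is
  BIDS-inspired but fixed by this package, since BIDS does not define
  phantom-session entities.
* The metric store is a flat, diffable CSV (fixed column order, full
  float round-trip precision, append-only with a duplicate-key flag)
  rather than a database — sized for the low thousands of sessions a
  study accumulates.
* EPI matrix, TR and phase-encode axis are configurable, defaulting to
  a 64×64 matrix, TR 2 s and phase axis y; the source protocol defers
  its exact sequence parameters to its resting-state protocol, so none
  are asserted.
* CLI exit codes: 0 success, 1 validation error, 2 I/O error, 64 usage
  error; every run logs package version, config hash and input digests.

## Known limitations

* No Weisskoff radius-of-decorrelation analysis, spatial-inhomogeneity
  maps or per-slice profiles; "spatial inhomogeneity" is listed in the
  source protocol without a definition and is deliberately not invented
  here.
* Spikes are whole-volume; per-slice artifacts are out of scope.
* Placement detection reports the offset only — root-cause separation
  of placement vs hardware remains a human decision, surfaced via the
  offset column next to the flags.
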