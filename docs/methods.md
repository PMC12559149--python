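# Methods

## The measurement model

Lower-limb torsion is quantified on axial stacks as the angle between a
proximal and a distal reference line, each an undirected in-plane line
(defined mod 180°). All geometry lives in a single coordinate convention:
arrays are indexed `(z, y, x)` with z proximal→distal, +x patient-left and
+y posterior; angles are measured counterclockwise from +x in degrees and
normalised to (−90°, 90°]; left limbs are mirrored in x before any angle is
computed, so positive torsion means anteversion on both sides.

**Femoral torsion (Lee-style).** The femoral head and neck centers are
least-squares circle fits to the outer contour (8-connected boundary pixel
centers, in mm) of the femur mask on a head and a neck slice. The circle
fit seeds the algebraic (Kåsa) solution into Gauss–Newton iterations on the
radial residual Σ(dᵢ−r)², so the reported circle minimises the geometric
objective. The neck axis is the line through the two centers projected
axially. The distal reference is the common posterior tangent of the two
femoral condyles: the posterior convex-hull edge whose endpoints lie in
different condylar components, which is exactly the line first touched when
a line is advanced from posterior — an iterative shifted-line search and
the hull construction agree by convexity, and a test verifies the
equivalence against a 0.01°-step rotating-line sweep. Torsion is the
wrapped difference (neck axis − condylar tangent).

**Tibial torsion (Ulm-style).** Proximal reference: posterior tangent of
the tibial plateau. Distal reference: the line through the pixel centroids
of the distal tibia and fibula masks. Torsion = (plateau − tibio-fibular
axis), wrapped.

**Slice selection.** When no hints are given: head slice = hip slice of
maximal femur area; neck slice = the slice distal to it with minimal femur
area among those above 25% of the head-slice area; condylar / plateau
slice = knee slice of maximal femur / tibia area; distal slice = ankle
slice of maximal tibia area. Phantoms carry designated slice indices so
geometry tests can bypass this heuristic. If a condylar mass arrives as a
single connected component (possible at coarse spacing or after
segmentation dilation), it is split by the vertical line through its
centroid before the tangent search.

**Failure semantics.** `measure_limb` never raises: each landmark failure
(empty mask, non-separable condyles, coincident centers) is recorded with
its reason, success is true only if both angles were computed, and a
partially successful limb still reports the angle it obtained.

## Phantoms

Each synthetic limb is built from primitives with analytically known
landmarks: femoral head = truncated sphere; neck = oblique circular
cylinder whose in-plane drift direction *is* the neck axis; condyles and
tibial plateau = two posterior circular lobes constructed to share a
posterior tangent of prescribed angle; distal tibia = ellipse; fibula =
circle offset along the tibio-fibular axis. The knee stack keeps one empty
slice between femur and tibia — the joint space — which also keeps the two
bones 3D-disconnected for component-based segmentation. Truth angles
satisfy the defining relations exactly by construction; rasterisation is
the only error source, and the recovery tests bound it (< 2° at 0.6 mm
in-plane spacing; in practice ≈ 0.1°).

T2-like contrast assigns bright marrow (default mean 160), a dark cortical
rim (25) of configurable thickness (default 0.8 mm, rendered by in-plane
erosion), and intermediate soft tissue (80), plus seeded Gaussian texture
(SD 6) and clipping at 0. Default spacing is (3.0, 0.6, 0.6) mm on
12×160×160 stacks, emulating anisotropic 2D TSE acquisitions; the
experiment pipeline uses a coarser (3.0, 1.2, 1.2) mm / 96×96 geometry
that keeps a full cohort run fast while preserving sub-degree clean-stack
recovery. Cohorts draw torsion parameters uniformly: femoral torsion
0–25°, tibial torsion 20–45°, condylar and plateau angles ±5° — ranges
chosen to span clinically reported adult variation.

What the phantoms deliberately do **not** model: realistic bone surfaces,
cartilage, muscle/fat compartments, partial-volume tissue mixtures, coil
profiles, or pediatric morphology. Passing tests therefore demonstrate
correctness of the geometric and statistical machinery and qualitative
artifact behaviour, not clinical-grade segmentation difficulty: the
stand-in segmenter's absolute Dice values on phantoms say nothing about a
trained network on patients.

## Artifact model

All volume-level operators are identities at zero intensity and return
real, finite arrays (FFT convention: DC at index 0; phase-encode axis = y).

* **Ghosting**: every g-th phase-encode line (DC excluded) scaled by
  (1−s); g ∈ {2..4}, s per severity.
* **Spike**: a complex point of magnitude s·max|K| added at a k-space
  position and its Hermitian mirror, yielding pure cosine stripes.
* **Motion**: k-space assembled line-wise from rigidly
  rotated/translated copies of the slice; state 0 is the untransformed
  anatomy and a schedule partitions the phase-encode lines.
* **Blur / bias / noise**: Gaussian blur with σ in mm, multiplicative
  exp-polynomial bias field (degree 3, coefficients ∝ scale), additive
  Gaussian noise as a fraction of image maximum.

Severity presets (mild / moderate / severe) use strictly increasing
ranges: ghost s 0.1–0.3 / 0.3–0.6 / 0.6–0.9; motion ≤2°,2 mm ×1 / ≤5°,5 mm
×2 / ≤10°,10 mm ×3; blur σ ≤0.5 / 1.0 / 1.5 mm; bias ≤0.1 / 0.2 / 0.3;
noise ≤2 / 5 / 8% of max; spike s 0.05–0.15 / 0.15–0.3 / 0.3–0.6. These
are package-defined, configurable stand-ins graded to produce visually and
quantitatively monotone corruption. The sampler includes each artifact
independently (probability 0.5; spikes 0.02) and logs a self-contained
recipe, so any corrupted stack is exactly reproducible from its seed.

Artifacts are volume-constant by default — emulating in-silico corruption
that is identical across slices — and never move the label maps, since
they corrupt the signal, not the nominal anatomy. The one exception is the
ankle through-plane emulation: per-slice random rigid offsets (scaled with
severity: ±1 mm/1°, ±2.5 mm/2.5°, ±5 mm/5°) model motion between slice
acquisitions and do move anatomy, which is what makes registration-based
recovery measurable.

## Segmentation stand-in

Automatic Otsu threshold (an explicit quantile is honoured when given) →
in-plane opening (≥1 px, so isolated noise voxels can never 3D-bridge two
bones across the joint space) → 3D connected components → minimum-size
filter → per-component dilation by the cortical-rim thickness (the bright
marrow threshold excludes the dark rim; dilation recovers it) → rule-based
bone codes: hip = femur only; knee: most proximal component = femur,
largest remaining = tibia, smallest = fibula; ankle: larger = tibia,
smaller = fibula. Unusable images yield an empty label stack with a
flag — never an exception. Dice uses the convention empty∩empty = 1,
empty∩non-empty = 0.

## Registration

Slice-wise 2D similarity registration maximises joint-histogram mutual
information (32 bins, intensities clipped to the 1st–99th percentile,
inputs smoothed by σ=1 px) via regular-step gradient ascent: finite-
difference gradient, step halved on gradient-direction reversal, stop
below step tolerance. Initialisation matters more than the ascent:
translation is seeded by cross-correlation (plain normalisation — the
"phase" variant is unreliable on smooth real-valued images), rotation by a
±12° grid with the translation re-estimated at the best rotation.
Transforms act about the slice center, translations in mm. Recovery of
random transforms (≤10°, ≤10 px) is accurate to ≪0.5° / 0.5 px on phantom
slices. The pipeline applies registration only to motion-affected ankle
stacks, in the opt-in "preprocessed+registration" strategy: per-slice MI
optimisation is the most expensive stage of the pipeline, and the default
experiment is designed to run in seconds per participant.

## Statistics

ICC is fixed to the two-way random-effects, absolute-agreement,
single-rater form (ICC(2,1)), computed from the explicit two-way
mean-squares decomposition with the standard F-bound confidence interval;
pingouin serves as an independent oracle in tests, never as the
implementation. RM-ANOVA is the one-way within-subjects decomposition
(incomplete rows dropped and counted; Shapiro–Wilk residual normality is
an advisory flag, never a gate). Tukey HSD uses the studentized-range
distribution, with the within-subjects error mean square when invoked in
the repeated-measures context. The mixed model is a REML random-intercept
fit (statsmodels) with treatment-coded fixed factors relative to declared
reference levels; singular fits are flagged, not hidden. Significance is
stratified ns / * / ** / *** at 0.05 / 0.01 / 0.001.

The a-priori sample-size calculator uses the within-factors RM-ANOVA
noncentral-F power with λ = f²·n·m/(1−ρ), df₁ = m−1, df₂ = (n−1)(m−1) and
sphericity ε = 1, returning the smallest n whose power reaches the target.
With f = 0.25, α = 0.05, power = 0.80, ρ = 0.6 it returns n = 23, 19, 17
for m = 3, 4, 5 repeated measurements — a five-acquisition design needs 17
participants. The number of measurements is an explicit argument because
the answer depends on it strongly.

## The experiment

`run_experiment` generates a seeded cohort (default 20 participants,
bilateral, severity plan none/mild/moderate/moderate/severe echoing a
five-acquisition design with graded motion), corrupts every stack,
evaluates the configured strategies — `raw` (segment the corrupted stack),
`preprocessed` (crop + z-score first; identical in outcome for the
scale-invariant stand-in segmenter, so this pair forms a built-in null
comparison), and optionally `preprocessed+registration` — and tabulates:
per-record Dice; Dice by severity × strategy × region; torsion success
rates with counts; measured-vs-truth MAD/ICC/r; and the mixed-model
coefficient table (severity and joint level relative to none/hip). A
single master seed derives every stage seed; identical seeds give
byte-identical CSVs. Severity is known from the simulation recipe — the
reader-grading step of a clinical study is deliberately replaced.

At phantom scale the experiment reproduces the qualitative finding that
motivates the whole exercise: Dice and torsion success fall monotonically
with severity and angle error rises, with the tibial (ankle-dependent)
measurement collapsing at severe corruption while the femoral one largely
survives — and the mixed model attributes a large negative coefficient to
severe artifacts.

## Numerical choices and degenerate inputs

* Angle wrapping: `a % 180`, then subtract 180 if > 90 — lands exactly in
  (−90, 90]; ties in slice auto-selection resolve to the first slice.
* Circle fits require ≥3 non-collinear points; collinearity is detected by
  rank deficiency.
* Posterior tangent requires two components; a merged mass is split at its
  centroid column first, and a tangent touching only one component is an
  error, not a guess.
* MI of a constant image is defined as 0 with a degenerate flag; a
  non-finite objective aborts that slice's registration with a status,
  never the stack.
* Dice denominators of 0 (both masks empty) return 1.0 by convention.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; no global state.

## Known limitations

The stand-in segmenter is intentionally simple; absolute Dice values are
not comparable to a trained network's. Artifact presets are plausible but
not calibrated against scanner data. The ellipse-based variant of the
distal tibial reference line is not implemented (the centroid construction
is); 3D neck-axis estimation, deformable registration, and
metal/chemical-shift/Gibbs/aliasing artifacts are out of scope.
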