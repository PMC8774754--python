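# Methods

## The measurement

A transverse TEM section of a motile cilium shows nine peripheral
microtubule doublets around a central pair. The *axonemal circumference*
is defined as the closed curve joining the centers of the nine A-tubules.
`axosym` turns the visual scoring rule — a doublet counts as rotated
when its B-tubule sits outside the circumference — into a quantitative
decision:

1. Fit the circumference through the A-tubule centers.
2. For each doublet, compute the signed orthogonal distance (*clearance*)
   of the B-tubule center from the fitted curve (positive = outside).
3. Call the doublet **rotated** iff clearance ≥ `kappa * r_b`, with
   `kappa = 0.5` by default — half the B-tubule protruding. Equality
   counts as rotated. Only outward displacement counts; inward clearance
   is recorded but never scored, matching the published illustrations,
   which show only outward swing.
4. Call a **symmetry break** iff strictly more than 3 doublets are
   rotated (count ≥ 4).
5. Per patient, **AA% = 100 × breaks / assessable sections**. Sections
   with microtubular disorganization, or with fewer than 8 of 9 doublets
   localized, are excluded from numerator and denominator alike; the
   8-doublet floor slightly biases toward symmetry and is flagged in
   reports.

`kappa` is exposed because the original observers drew the line by eye:
nothing in the published protocol says whether they referenced the
B-tubule's edge or center, so the protrusion fraction is genuinely a
free calibration. 0.5 is robust to center-localization error of a pixel
or two at the default scale while matching the published figures.

## Circumference fitting

Cross-sections are often obliquely cut, so the default model is an
ellipse with a circle fallback (`kind="auto"`): an ellipse is fitted when
≥ 6 points are available and kept when its eccentricity is ≤ 0.8,
otherwise a circle is used. The fit minimizes *geometric* (orthogonal)
residuals, not an algebraic conic form: an algebraic seed (Halir–Flusser
via `skimage`, with a circle-fit fallback when near-circular data defeats
the conic solver) is refined by Levenberg–Marquardt on the signed
orthogonal distances. Point-to-ellipse projection uses a dense angular
scan (128 samples) followed by Newton iteration on the stationarity
condition of the squared distance — robust for interior points and
non-unique projections, accurate to ~1e-12. Circles use a Kåsa algebraic
seed plus the same geometric refinement.

On noiseless 9-point data the fit recovers parameters to ~1e-15 relative
error; on jittered data it matches a derivative-free brute-force
minimizer of an independent polyline-distance objective to within the
polyline grid resolution (both verified in the test suite and the
reproduction script).

Tilt angles (between the A→B axis and the curve tangent at the A-center's
projection) are reported per doublet as a descriptive quantity; the
rotation decision itself uses only clearance.

## Defect classification

Per section, ODA (resp. IDA) absence is called when at most `arm_min = 2`
of the doublets with an evaluable arm flag still bear the arm — the
per-doublet threshold is a necessary operationalization because published
protocols score whole sections; it is configurable. A central-complex
defect is any central microtubule count ≠ 2. Per patient, the modified
BEAT-PCD bands apply: Class 1 when ODA (or combined ODA+IDA) absence
exceeds 50% of sections; Class 2 when either lies in the inclusive band
25–50%, or when central defects exceed 25% of sections (the central
band carries no published percentage; 25% aligns it with the other
Class-2 band and is configurable); otherwise no defect. Diagnostic-grade
calls expect ≥ 50 sections; below that a low-coverage warning is issued
rather than a refusal.

## The synthetic generator

The generator emulates what the scoring stages consume, not electron
optics. Per section it samples an ellipse (semi-major ~ N(105, 5) px,
aspect ratio uniform on [0.88, 1.0], random orientation), places nine
A-centers at 40° nominal spacing with angular jitter (sd 2°) and
isotropic positional jitter (sd 1 px), draws the number of rotated
doublets from a configurable distribution over 0..9, and swings each
doublet's axis outward from the local tangent by a tilt drawn from
|N(0°, 4°)| (aligned) or N(35°, 8°) truncated to [15°, 75°] (rotated);
the B-center sits at `r_a + r_b` from the A-center along that axis.
Section-level defect flags (arm absence, central-pair loss,
disorganization) are independent Bernoulli draws. Everything is
reproducible from the scene seed.

Scale: 1 px = 2 nm, a plausible convention for ~×530,000 prints. The
tubule radii (r_a = 12 px, r_b = 14 px) are deliberately generous for
legibility of the rendered rings; the ring radius (105 px) is chosen so
that the ratio of the intra-doublet A–B spacing (26 px) to the
inter-doublet gap matches real axonemes (~1 : 1.5) — with a smaller ring
the B-to-neighboring-A distance collides with the A–B spacing and no
pairing rule, human or algorithmic, could separate doublets.

Rendering: dark walls on a light background (positive TEM contrast).
A-tubules are complete annuli, B-tubules C-shaped annuli opening toward
their A-tubule, dynein arms small hook sectors on the A-tubule (ODA
outward, IDA inward), the central pair two annuli at the section
centroid; Gaussian blur (psf sd 2 px) and additive Gaussian noise
(sd 0.05 on a [0, 1] scale) are applied last.

What the generator does **not** emulate: membrane and matrix texture,
stain gradients, neighboring cell structures, compound/swollen cilia,
partial sections, or multi-axoneme fields (the detector assumes one
pre-cropped axoneme per image). Passing image benchmarks therefore
demonstrates correctness of the geometric reasoning and robustness to
blur/noise, not clinical-grade detection on raw micrographs.

## Image analysis

Ring candidates come from annular matched filters (mean wall darkness on
a circle of radius r minus the interior-disk mean) over r ∈ [7, 16] px,
followed by non-maximum suppression at 1.2·r_min separation, sub-pixel
quadratic peak refinement, and a perimeter-completeness screen
(≥ 0.65 of sampled perimeter above half the wall level) that rejects arc
fragments such as dynein-arm hooks. Candidates near the centroid count as
the central pair; peripheral candidates are paired by mutual nearest
neighbor within ±30% of the expected A–B spacing. Within a pair the more
complete ring is the A-tubule (B is C-shaped); when completeness scores
tie within 0.05 the member farther from the provisional center is taken
as B. A section whose pairing is inconsistent with 9+2 geometry
(pair count ≠ 9, or > 1 unpaired peripheral candidate) is flagged
disorganized and refused by the assessment stage rather than silently
fitted. Arm presence is never inferred from images; arm flags enter via
coordinate annotations only.

## Validation design and problem sizes

* **Round trip** — in the well-separated regime (rotated tilt 40°, zero
  aligned tilt, no jitter) the coordinate pipeline must reproduce the
  generated rotated count exactly: 100 sections for each k in 0..9.
* **Image benchmark** — 200 rendered sections at default noise, half
  drawn with ≥ 4 rotated doublets. Accuracy is scored against the
  *coordinate-level* call on the true coordinates: with the realistic,
  overlapping tilt distributions an "aligned" doublet occasionally
  crosses the decision boundary for real (which is precisely why real
  control patients show nonzero AA), so the drawn label is not an
  error-free reference for the image stages, whereas the coordinate-level
  call isolates detection fidelity. Agreement with the drawn labels is
  reported alongside. Specificity uses 100 zero-tilt sections; a noise
  sweep (sd 0.05, 0.25, 0.5; 60 sections each) checks that accuracy
  degrades monotonically.
* **Cohort simulation** — 20 patients × 50 sections at break probability
  0.5, generated with zero aligned tilt so the scored AA is exactly the
  Binomial(50, 0.5) truth; the mean is checked against 50% within 3
  binomial standard errors and every AA against the 2% granularity grid.

Problem sizes were chosen to keep each benchmark statistically meaningful
at desk scale; all regenerate from a single seed.

## Numerical conventions and edge cases

* Image coordinates (origin top-left, y down) are converted to a y-up
  mathematical frame before any geometry; all angles are CCW from +x.
  Doublet index 1 is the doublet nearest 12 o'clock, numbering clockwise
  as seen on the image.
* AA% and defect percentages are reported to one decimal in machine
  output; published per-patient tables print integers.
* Quartiles use linear interpolation between order statistics (the common
  statistical-software default); the convention is configurable in
  principle but cannot be adjudicated from the published summary tables,
  whose group sizes (n = 19/5/11 and 13/19/2) are not reconcilable with
  the 40 transcribed participants — those printed means are therefore
  deliberately not reproduction targets.
* Degenerate inputs raise typed errors: fewer than 3 (circle) / 5
  (ellipse) points, collinear configurations, coincident A/B centers,
  negative `kappa`. Sections that cannot be assessed (disorganized,
  < 8 localized doublets, < 12 ring candidates) carry an explicit
  not-assessable status instead of a fabricated call.
* Boundary rules: clearance exactly at `kappa * r_b` is rotated; ODA
  absence at exactly 25% or 50% of sections is Class 2; a rotated count
  of exactly 3 is *not* a break.

## Known limitations

* The detector is validated only on synthetic renders; real micrographs
  add texture and crowding it has never seen.
* `kappa` and the per-doublet `arm_min` threshold are calibration
  choices, not published constants; both are surfaced in the config.
* Inward-rotated doublets are recorded but never counted, following the
  published illustrations; if inward rotation turns out to be
  biologically meaningful the clearance sign is already available.
* The per-patient tables are transcriptions; the study deposited no raw
  images, so image-level agreement with the original observers cannot be
  measured.
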