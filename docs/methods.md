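# Methods

## Problem setting

Free-breathing real-time cine CMR acquires a long, non-gated frame stream
per short-axis slice. Within one slice the cardiac and respiratory cycles
are sampled jointly; across slices they are not synchronized. Accurate
volumetry requires, per slice, an ED and an ES frame captured in the same
respiratory state — conventionally end expiration, whose quasi-static
plateau occupies a longer fraction of the breathing cycle than end
inspiration. `respsort` recovers the respiratory signal retrospectively
from the images themselves (no ECG, no plethysmography), classifies the
respiratory extrema, and drives frame selection and summation-of-discs
volumetry from there.

## Respiratory embedding

The diaphragm ROI sub-images `x_1 … x_N` are treated as samples of a
one-dimensional manifold parameterized by diaphragm displacement. The
1D Laplacian Eigenmaps curve is the generalized Fiedler vector of the
weighted graph Laplacian: minimize `φ(y) = Σ_ij W(i,j)(y_i − y_j)²` with
`yᵀDy = 1`, `yᵀD1 = 0`, solved as `L y = λ D y` for the smallest nonzero
λ. Weights are Gaussian, `exp(−‖x_i − x_j‖²/2σ²)`, on connected pairs and
0 elsewhere.

**Graph connectivity (a deliberate design choice).** Three constructions
are provided:

* `temporal` — each frame connects to its k temporally nearest neighbours
  (⌊k/2⌋ preceding, ⌈k/2⌉ following, truncated at the boundaries,
  symmetrized by union).
* `intensity` — classical k-NN in image space.
* `hybrid` (pipeline default) — the union of both edge sets.

A purely temporal band graph is path-like, and by Sturm oscillation theory
its first nontrivial generalized eigenvector has exactly one sign change —
it is a monotone function of *acquisition time*, whatever the weights. It
therefore cannot oscillate at the respiratory frequency; empirically its
Spearman correlation with frame index is ≈ 1.0 and with diaphragm
displacement ≈ 0.04, at every k tested (10–200). Intensity-space edges tie
together same-displacement frames from different breaths, collapsing the
graph geometry onto the respiratory coordinate; the temporal band then
regularizes the manifold against noise. With the hybrid graph the embedded
curve tracks true diaphragm displacement with Spearman |ρ| ≈ 0.99 on
noise-free and 20 dB phantoms alike. The temporal-only and intensity-only
graphs remain available for study.

**Parameter defaults.**

* `k = 10` (both edge families). At 32–37 ms temporal resolution the
  temporal band spans ≈ 0.35 s — short against a respiratory half-cycle,
  long enough to smooth frame noise. The intensity k-NN at 10 keeps the
  graph sparse while guaranteeing cross-breath links for ≥ 2 acquired
  cycles.
* `σ²` — self-tuned as half the median squared edge distance. When the
  plain median is zero (noise-free plateaus produce identical frames) the
  median of the *positive* distances is used; if every edge distance is
  zero the sequence is degenerate and rejected. A fixed override is
  accepted.
* Eigensolver — ARPACK shift-invert (`σ_shift = −10⁻³·mean degree`) on the
  sparse generalized problem, with a larger-subspace retry and an LOBPCG
  fallback (constant mode deflated by constraint); the residual and solver
  are recorded in the curve provenance. For N ≤ 50 the solution matches a
  dense `scipy.linalg.eigh(L, D)` brute force to < 10⁻⁸.
* Self-edges are excluded; boundary frames keep truncated neighbourhoods
  (time does not wrap).

**Orientation.** The embedding sign is arbitrary. The curve is flipped so
maxima mean end expiration using the intensity-weighted vertical centroid
of the ROI: the diaphragm is most cranial (smallest row index) at end
expiration, so the oriented curve must anticorrelate with centroid row.
If |r| < 0.3 a plateau-duration heuristic is used (the extreme neighbourhood
holding more frames is expiration); failing both, orientation is
`undetermined` and downstream processing requires a manual assignment.

## Extrema, windows, frame selection

The curve is smoothed by a centered moving average of width ≈ 0.25 × the
respiratory period (period from the dominant nonzero FFT frequency; the
width suppresses cardiac-frequency leakage without blunting extrema).
Maxima/minima need prominence ≥ 0.2 × curve range and separation ≥ half a
period; alternation is enforced by keeping the more extreme of any
same-type pair. Indices refer to the unsmoothed frame grid.

State windows use half-widths of ±15 (expiration) and ±10 (inspiration)
frames at rest, ±8/±5 during exercise, clipped to the acquisition; windows
of adjacent opposite extrema are truncated at their integer midpoint (the
earlier window keeps the midpoint frame).

ED/ES selection uses a lumen proxy: pixel count above an Otsu threshold
(computed once over the whole cropped LV sub-sequence) times pixel area —
a bright-blood (bSSFP-like) assumption. Within each window ED is the proxy
argmax and ES the argmin, ties broken toward the window centre and then
toward the later frame; across windows of one state, the globally largest
ED and smallest ES are kept, possibly from different breaths. Slices where
any stage fails are carried through flagged `incomplete` rather than
dropped. QC additionally flags adjacent-slice ED pairs with zero-normalized
cross-correlation ≥ 0.98 as potential duplicates (flag-only; removal is a
user decision) and compares stack length (`slices × (thickness + gap)`)
against a 4-chamber LV length, flagging a mismatch beyond one slice
spacing.

## Quantification

Summation of discs: volume = Σ areaᵢ × (thickness + gap)/10 (cm² → ml);
LVM = (epi − endo volume) × 1.05 g/cm³ from the ED delineations;
SV = EDV − ESV exactly; EF = SV/EDV. Papillary/trabecular exclusion is a
property of the input masks — the package never re-segments. BSA is an
input (a Mosteller helper exists but is never applied implicitly).
Heart rate averages the per-slice mean ED-to-ED interval over three slices
(beginning/middle/end of the stack), with ED events detected as lumen-proxy
peaks over the whole acquisition. Phase-contrast stroke volume is the
trapezoidal net flow between the first and last diastole markers divided by
the number of beats, on the native sample grid (no resampling assumptions).

## Agreement statistics

Bland–Altman: bias = mean difference, SD with n−1 denominator, limits of
agreement = bias ± 1.96 SD. ICC: single-measure two-way mixed model from
the two-way ANOVA mean squares; the default definition is absolute
agreement — the variant most commonly reported from SPSS — with consistency
available; 95% CIs follow McGraw & Wong's F-based formulas, cross-checked
against pingouin. CoV defaults to the within-subject form,
(SD of paired differences / √2) / grand mean, with the simple SD(d)/mean
form behind a flag.

## Synthetic phantom

The phantom emulates the features the pipeline exploits, with exact truth:

* **Respiration** — raised-cosine displacement of a bright-lung/dark-abdomen
  edge, with a flat plateau (default 0.3 of the cycle) around the
  expiratory extreme implemented by time-warping the phase; defaults:
  period 90 frames, amplitude 8 px, optional cycle-period jitter. The
  plateau reproduces the physiological asymmetry that makes the ±15/±10
  window split meaningful.
* **Heart** — a bright blood disc (endo radius interpolating smoothly
  between ED and ES values with a 1/3 systolic fraction; default period 27
  frames ≈ 63 bpm at 35 ms/frame) inside a mid-grey myocardial ring,
  translated with 0.4 × the diaphragm displacement. By default the
  epicardial radius co-varies so the ring keeps constant cross-sectional
  area (incompressible myocardium), making LVM comparable between ED and
  ES; a fixed-epicardium mode exists.
* **Through-plane content change** — a mild (±5%) respiratory-linked blood
  intensity modulation stands in for spins moving through the slice.
* **Noise** — i.i.d. Gaussian; `noise_sd_from_snr` converts a dB level
  against the diaphragm step (20 dB default in the validation suite).
* **Truth** — per-frame displacement, respiratory state labels (within 5%
  of peak-to-peak of an extreme), cardiac phase, analytic disc radii and
  areas; per-cycle extreme frames. True extrema whose neighbourhood
  (within-ε run) comes closer than a tenth of a period to the acquisition
  boundary are not counted: such an extreme is not identifiable from the
  data in principle, and prominence-based detection correctly ignores it.
  Stack truth includes closed-form EDV/ESV/epicardial volumes as sums of
  discs over the per-slice taper (ellipsoid-like, non-increasing scales).

What the phantom does **not** model: MR physics (coils, banding,
parallel-imaging artifacts), realistic anatomy, arrhythmia, in-plane
rotation or deformation, bulk patient motion. Passing the phantom suite
therefore demonstrates the pipeline's correctness under idealized contrast
and motion, not clinical robustness; on patient data the diaphragm may
leave the ROI (basal slices), for which the curve/extrema can be supplied
manually.

## Problem sizes in the validation suite

The validation suite and the reproduction script use an 8-slice stack with
500 frames/slice (≈ 5.5 respiratory cycles at period 90) and a 250-frame
cropped rerun — proportions mirroring a ~17 s acquisition at ~35 ms per
frame and its half-time crop. Masks for phantom quantification are
rasterized from the analytic disc geometry at the selected frames, playing
the role of manual delineation.

## Known limitations

* The intensity k-NN graph costs O(N²) distance evaluations; fine for
  N ≤ a few thousand frames, not tuned beyond that.
* Orientation needs either diaphragm contrast in the ROI or a plateau
  asymmetry; a perfectly symmetric breather with no centroid signal stays
  `undetermined`.
* Multi-frame DICOM is not read (single-frame series only); DICOM writing
  is out of scope.
* ED/ES selection assumes bright-blood contrast; dark-blood sequences would
  need a different lumen proxy.
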