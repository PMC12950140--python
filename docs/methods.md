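# Methods

This note documents the models and procedures implemented in `spinedyn`,
the choices made where the underlying analysis conventions are genuinely
open, and what the synthetic benchmark does and does not establish about
real data.

## The synthetic scene model

A scene describes one dendritic segment followed over an ordered list of
imaging sessions (default `BL, d3, d7, d14`, mirroring a baseline plus
3/7/14-day follow-ups).

**Geometry.** The backbone is a cubic spline through five control points
spanning the field along x with sub-micron lateral and axial excursions —
an apical dendrite segment lying nearly in the imaging plane. Default
field: 128 × 128 × 21 voxels at 0.18 × 0.18 × 1 µm
(≈ 23 × 23 × 21 µm), so a session renders in well under a second. The
shaft radius is 0.5 µm. Spines are placed at arc positions drawn from
jittered equal slots (guaranteed minimum arc separation, default 1.2 µm),
with sideways azimuths (±90° ± 25° from the shaft axis), elevations
0–30° from the imaging plane, protrusion lengths 1–2 µm and head radius
0.3 µm. With ten baseline spines on a ~20 µm segment the density is
≈ 0.5 /µm and per-interval event counts of 1–2 correspond to 10–20 %
turnover — literature-scale values for layer-2/3 apical dendrites; no
measured dataset fixes them more precisely.

**Identifiability constraints.** Two constraints make the programmed truth
well-posed for an observer (human or algorithmic) that identifies spines
by position:

* spine endpoints are at least 1.5 µm apart in 3-D — the axial FWHM of
  rendered structures; heads closer than the resolution limit are not
  individually countable;
* a spine gained at some interval is placed at least 3 µm (in arc) from
  any spine eliminated at the same interval. Without this, "gain + loss
  nearby" is indistinguishable from "persistence with drift" for any
  position-based correspondence; in practice that ambiguity is resolved by
  checking spine appearance by eye, which a geometric benchmark cannot
  emulate.

**Schedule.** The presence matrix realizes exactly the requested
per-interval loss/gain counts; losses are drawn uniformly from the spines
currently present. A lost spine stays lost (recurrent spines start new
tracks); schedules with reappearance can be enabled but are off by
default. Brightness multipliers are 1.0 at each spine's first session and
uniform in 1 ± 0.2 afterwards.

**Rendering.** Structures have a Gaussian radial profile
`A·exp(−ln2·(d/r)²)` so the half-width at half-maximum equals the nominal
radius, truncated at 2.5 r; overlapping structures combine by maximum,
which keeps per-spine brightness scaling exactly linear. The axial
half-width is floored at 0.75 µm for every structure: two-photon
excitation elongates all objects axially, and without the floor a
0.3 µm head whose centre falls between 1 µm z-planes would disappear
from the sampled stack, which real recordings do not show. Shaft
amplitude 100; spine head 100 × multiplier; neck 70 × multiplier (dimmer
necks give each spine a unique head maximum). The acquisition model is an
anisotropic Gaussian PSF (σ = 0.25, 0.25, 0.9 µm), a constant background
offset (default 10), Poisson shot noise on the blurred image and optional
Gaussian read noise. At the defaults the structure-to-noise ratio is
≈ 5–9. With all noise disabled the render is exact: voxels outside the
structure support equal the background offset.

## Backbone tracing

Tracing is seeded by two operator-style clicks near the segment ends (the
demo uses the true curve endpoints). The centreline is the minimum-cost
path on the 26-connected voxel graph restricted to voxels above
`background + 0.1·(max − background)`, with step cost = physical step
length divided by mean above-background intensity. Each path point is then
re-centred 3 times on the background-subtracted intensity centroid in its
normal plane (±0.8 µm window), smoothed with a 9-point moving average
(±0.9 µm at the 0.2 µm resampling step — wide enough to suppress the pull
of bright spine necks, narrow against the segment's gentle curvature),
and resampled at 0.2 µm.

The local radius is the in-plane half-width at half-maximum of the
perpendicular intensity profile. The *minimum* of the two opposite
half-widths is used — a spine on one side inflates that side's half-width,
while the other side still reads the true caliber — followed by a 5-point
rolling median along the arc. On clean straight tubes the traced
centreline deviates < 0.1 µm RMS from truth and the radius is recovered
within a few percent; under PSF blur the apparent radius grows to
≈ 0.57 µm for a 0.5 µm tube, which is the radius the inclusion geometry
should use on blurred data (the measurable tube surface).

Arc-length coordinates come from exact point-to-polyline projection
(vectorized over all segments; ties resolve to the lowest segment index).

## Session registration

In vivo, the field is re-located by the experimenter between sessions, so
only a small residual rigid shift is expected and rotation is neglected.
Registration is translation-only phase correlation in two stages: an
integer-voxel global search, then sub-voxel refinement (upsampled phase
correlation) computed on the cropped overlap only — content that slid out
of the field otherwise biases the fractional part at large shifts. The
quality score is the Pearson correlation of the overlap after the integer
shift; below 0.2 the result is flagged low-confidence and the pipeline
continues with a warning. Known shifts up to 25 % of the field are
recovered within ≈ 0.2 voxel per axis at realistic noise.

## Spine detection and attachment

Candidates are local maxima (3×3×3 footprint) of a lightly smoothed stack
(σ = 0.1, 0.1, 0.3 µm) above `background + 0.2·(max − background)`,
restricted to lie outside the backbone tube (lateral offset > local
radius + 0.3 µm) and within 3 µm of it. Peaks closer than 0.35 µm merge
onto the brighter one; survivors are localized to sub-voxel precision by
per-axis parabolic interpolation — unlike an intensity centroid this is
not dragged toward the neck or the shaft's blur ramp. A manual annotation
table, when provided, replaces automatic detection verbatim (endpoint
marking is manual in the original workflow; detection here is its
automated surrogate).

**Brightest path.** Each endpoint connects to the backbone along the
26-connected voxel path that maximizes the minimum intensity along it
(bottleneck criterion), with ties broken by shorter physical length and
then by a fixed voxel order — a widest-path Dijkstra over the admissible
region (voxels above background by 2 % of the dynamic range, within the
search radius). The bottleneck reading of "brightest" is scale-invariant
and robust to path length; its optimum is pinned against an independent
threshold-connectivity oracle in the tests. For geometry measurement the
search runs on a mildly smoothed, integer-quantized copy of the stack:
photon noise otherwise makes every bottleneck comparison unique, so the
shorter-path tie-break never engages and paths wander.

**Protrusion and elevation.** The measured polyline runs from the
sub-voxel endpoint through the path voxels; the crossing of the tube
surface is interpolated between the last voxel outside and the first
inside (per-point radii floored at the backbone-wide median), and the
protrusion length is the geodesic length from the endpoint to that
crossing. Elevation is the angle of the endpoint-to-attachment axis
against the xy plane.

**Secondary maxima.** A thin neck sampled on a coarse grid can bead into
extra local maxima, and a steep spine can leave a ghost maximum one
z-plane away. Such candidates lie on the brightest path of the true
endpoint (the head's path descends through its own neck), so marks whose
endpoint falls within a voxel neighbourhood of a longer mark's path — or
within 0.7 µm of its endpoint — are folded into it, keeping the largest
protrusion. Two genuinely distinct spines are unaffected at the
simulator's endpoint separations.

**Inclusion rule.** A mark is included iff protrusion > 0.72 µm
(strictly greater; 4 pixels at the 0.18 µm lateral pitch — the 4-pixel
figure is read in lateral pixels, consistent with the stated micron
value) AND elevation ≤ 45°. The elevation cutoff quantifies "primarily
parallel to the imaging plane", for which no numeric criterion is stated
anywhere; 45° is the natural midpoint and generous given that the 1 µm
z-step under-samples steep spines. Both thresholds are configurable.
Excluded marks are retained with `included=False`.

## Longitudinal matching and statistics

Included marks of consecutive sessions are matched on their arc positions
by a gated linear assignment: pairs farther than the tolerance (default
2 µm) are inadmissible, and every unmatched spine (a birth or a death)
costs the tolerance. This is the standard particle-tracking linker; unlike
a maximize-matches-first rule it cannot absorb a simultaneous gain and
loss through a chain of near-tolerance links. A tiny transpose-symmetric
tie-break term (−10⁻⁹·sᵢ·sⱼ) makes the matched pairs unique, preferring
the non-crossing pairing among cost ties, so swapping session roles
exactly exchanges additions and eliminations. Manual correspondence
overrides force individual links; a duplicate manual link is rejected.
Tracks are chains of consecutive matches; a spine absent in one session
and present later starts a new track.

Density is included spines per µm of backbone over a chosen arc interval
(default: the full traced extent). Dynamics ratios per interval, with
`N_prev` spines at the earlier session, `G` gained and `L` lost:
addition `G/N_prev`, elimination `L/N_prev`, turnover `(G+L)/(2·N_prev)`
— the turnover definition is the standard one in longitudinal spine
imaging; the ratios are computed against the immediately preceding
session by default, with everything-vs-baseline available as a switch
(both conventions appear in the literature and the source convention is
not stated). `N_prev = 0` leaves the interval's ratios undefined (NaN,
serialized as null).

## Intensity chain

Three disjoint ROIs per spine and session: the **spine ROI** is a
0.4 µm-radius cylinder around the endpoint spanning ±1 z-plane of its
brightest 3-plane window; the **shaft ROI** is the backbone tube within
±1 µm of the attachment arc in its own brightest z-window (spine voxels
excluded); the **background ROI** is a 0.5 µm disc displaced 2.5 µm from
the attachment point on the side opposite the spine. Overlapping ROI
construction flags the measurement invalid. The normalized intensity is
`(spine − background) / (shaft − background)`; dividing by the shaft
cancels session-wise illumination and expression drift, which is why the
programmed brightness multiplier is recoverable from renders at all.
Per-track series divide by the baseline value; tracks absent at baseline
are excluded from the series. Group mean ± SEM per session, the empirical
CDF and a tracks × sessions matrix are reported.

## What the benchmark shows — and does not

On noise-free renders the full pipeline reproduces programmed counts,
densities, and addition/elimination/turnover ratios exactly, and recovers
group-mean brightness multipliers within ~3 %. Under the full acquisition
model (PSF + shot noise, SNR ≈ 5–9) pooled endpoint precision and recall
are ≥ 0.9, suite-mean ratio errors are ≤ 0.05 (a single missed spine in a
10-spine scene moves that scene's ratio by 0.1, so per-scene exactness is
not a meaningful bar at this SNR), and per-session group-mean brightness
recovery is within ~15 %; individual tracks can err by more when a dim or
steep head is localized to its neck.

The simulator does **not** model motion within a session, bleaching,
vasculature shadows, branching arbors, or appearance differences between
spines — precisely the cues a human proofreader uses. Passing these tests
therefore validates the geometry and bookkeeping of the analysis, not
robustness to every failure mode of real recordings; the manual-annotation
and manual-correspondence overrides exist for exactly that reason.

## Numerical and engineering choices

* Arrays are `(z, y, x)`; physical points `(x, y, z)` µm; voxel centres at
  `index × pitch`. On-disk formats always store µm.
* All randomness flows through `numpy.random.default_rng` seeded from the
  scene seed (and session index for renders); identical seeds give
  byte-identical scenes, stacks and reports.
* Background is estimated as the stack median (structures are sparse).
* Degenerate inputs: an endpoint already on the tube yields zero
  protrusion; an empty spine list yields an empty, valid truth table; a
  session pair with no prior spines yields null ratios; sub-threshold
  scenes produce a valid all-zero report.
* Problem sizes in the test suite (10-spine scenes, 128×128×21 stacks,
  10-seed noisy batteries) were chosen so the whole suite and the
  acceptance script each run in minutes on one CPU while still exercising
  every stage end to end.
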