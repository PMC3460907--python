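# Methods

## Scope and model of the data

`flystrip` quantifies graded mRNA expression along the antero-posterior
(A-P) axis of early fly embryos from colorimetric whole-mount in situ
hybridisation (WMISH) image sets. Per embryo the raw data are up to four
registered 8-bit RGB images: a 10x DIC image (segmentation source), a 10x
bright-field image (expression source), a 10x nuclear counterstain (used by
experts for staging) and a 40x membrane-detail image (staging of cycle-14A
subdivisions). The pipeline output is, per embryo, an expression profile
(per-channel mean intensity vs. percent egg length, %EL, 0 = anterior) and
a set of labelled expression-domain boundaries; per gene, slope and time
class the package aggregates a median boundary and space-time tables of
boundary midpoints.

The method measures **boundary positions only**. Colorimetric staining is
enzymatically amplified and easily saturated, so relative expression
*levels* between domains are not comparable across embryos and are not
reported; min-max normalisation is applied per profile for display only.

## Segmentation

The embryo mask is produced from the DIC image by a fixed 14-stage sequence
of classical operations: gray conversion, gamma compression (exponent
0.08), inversion, Sobel gradient magnitude, threshold at 6, two dilations,
border-blob removal, two more dilations, hole filling, border-blob removal,
conditional removal of blobs smaller than `H*W/beta` (beta = 13.0),
Gaussian smoothing (sigma = 31 px, kernel truncated at a per-axis tail mass
of 1e-3), re-threshold at 145, and a final conditional blob removal. Every
intermediate is recorded under its stage name for audit. The strong gamma
makes the edge detector respond to the dark embryo rim rather than to
illumination gradients; the dilations close the rim into a ring whose
interior is filled; the blur/re-threshold pair smooths the mask edge, with
the threshold at 145 (slightly above mid-gray) trading a ~5 px erosion
against the ~5 px dilation growth.

Conventions the operations rely on: blobs are 8-connected, dilation uses a
3x3 square element, holes are 4-connected background (the topological dual),
the grayscale conversion is an unweighted channel mean (configurable
weights), and Sobel borders replicate edge pixels so a flat border produces
no spurious edges. The smoothing stage returns float intensities so the
subsequent threshold acts on exact smoothed values; intermediates are
rounded only when exported as PNG.

Degenerate inputs: images smaller than 3x3 are rejected; if the foreground
vanishes at any stage the error names that stage. If several blobs survive
the size cut they are all kept and the mask quality is flagged
`not good` (the manual rating vocabulary is `good` / `ok` / `not good`).

## Orientation

The A-P axis angle is the major principal axis of the foreground pixel
distribution, from central second moments, in (-90, 90] degrees (y-up
convention). Rotation is about the image centre with bilinear
interpolation (the original tool's interpolation and centre are
undocumented; image centre keeps all registered images on one canvas), the
mask is re-binarised at 128 afterwards, and all images are cropped to the
tight bounding box of the rotated mask. An isotropic mask (no defined
axis) yields 0 degrees with a warning rather than an error, so round
debris still crops. Anterior-left / dorsal-up cannot be inferred reliably
from blastoderm images, so horizontal/vertical flips are manual inputs
(CLI flags or a per-embryo CSV).

## Profile extraction

The midline is the morphological skeleton of the mask; the *main branch*
is the longest geodesic path between skeleton endpoints (8-connected graph,
Euclidean step weights), a definition chosen because short spurious side
branches must not deflect the axis. Five knots are placed at arc-length
fractions {0, 1/4, 1/2, 3/4, 1} of the main branch — endpoints included to
maximise coverage before extrapolation — and a natural cubic spline is
drawn through them. Beyond the outer knots the curve follows the quadratic
Lagrange polynomial through the three nearest knots per side (lowest
degree that captures midline curvature without oscillation), evaluated out
to the mask's horizontal extent. Manual knot dragging in the original GUI
is replaced by an optional knot-override table.

The extraction strip spans 10% of the D-V minor axis (5% above and below
the midline), where the minor-axis length is the mask's maximal vertical
extent — exact for an oriented embryo. For every pixel column in the
mask's horizontal extent the mean R, G, B over the strip rows is one
profile sample; columns map linearly to [0, 100] %EL.

Stain signals follow the colorimetric conventions: NBT/BCIP (purple) is
read from the red channel, FastRed as green minus red, clipped at zero
(the difference can go negative in unstained noise). An `invert_signal`
option (255 - channel before the formula) is provided for data where the
stain darkens rather than raises the extracted channel; the synthetic
generator emits images consistent with the direct formulas by default.

## Boundary splines

A domain boundary ("slope") between user-chosen outer edge x0 (signal
first distinguishable from background) and inner edge x2 (plateau
attained) is the cubic spline through (x0,y0), (x1,y1), (x2,y2) with first
derivative clamped to zero at both ends. x1 is the midpoint of x0 and x2;
all y values are read from the nearest profile sample (profiles are
per-column discrete). The fitted spline is a single C2 clamped cubic
through the three knots, which in particular satisfies C1 continuity at
x1. Boundaries carry gene, integer slope id, polarity
(anterior/posterior) and stain channel (purple/red) labels so homologous
boundaries can be compared across embryos and time.

Window placement is deliberately manual (the one manual step of the
workflow); `suggest_window` only proposes a candidate — inner edge where
the smoothed signal reaches 90% of the plateau-above-background amplitude,
outer edge where it drops below background mean + 2 SD (floored at 5% of
the amplitude for noise-free profiles), background estimated from the
lowest quartile of smoothed samples. These thresholds are conveniences of
this implementation, not measured properties of the original tool.

## Aggregation

Boundaries grouped by gene, slope, polarity and time class are summarised
by independent medians of the start and end knots (even counts: mean of
the central pair); the middle knot is re-placed at the midpoint of the
median end knots and the clamped spline refitted on the median knots
(whether the original re-reads y1 from a median profile is unstated).
Variability datasets return the individual min-max-normalised splines plus
the median per group; with more than one gene selected only medians are
returned. Space-time tables list the median-boundary midpoints x1 ordered
by developmental time. Time classes are validated metadata (cycles C1-C13
and C14A, the latter subdivided T1-T8); staging itself remains an expert
task and is not automated.

## Synthetic fixtures

The generator renders all four image types for an elliptical embryo with
exact ground truth (mask, angle, midline, boundary positions). Defaults
are one embryo of semi-axes 500 x 190 px on a 1036 x 1360 px canvas — an
egg spanning most of a 10x wide-field frame — background 140, interior
texture SD 18, and a 4 px dark rim (level 45) immediately inside the
ellipse boundary. The rim produces the closed Sobel ring the mask pipeline
needs, and placing its outer edge on the ground-truth ellipse lets the
pipeline's dilation growth and blur shrinkage cancel, as they do on real
rims. Expression domains are logistic ramps
`plateau * (sigmoid((u-a)/s) - sigmoid((u-b)/s))` in %EL, written into the
red channel (NBT) or as green-over-red excess (FastRed), so the half-maximum
crossings of the extracted signals sit at the declared boundaries.

Noise of total SD `noise_sd` is split 20% i.i.d. per-pixel and 80% smooth
illumination mottle (correlation length 6 px). This emulates well-exposed
wide-field images, where uneven illumination dominates over sensor noise.
It is a deliberate modelling choice with consequences: a hypothetical
image whose noise were entirely i.i.d. at SD 10 would trip the Sobel
threshold across the whole background and no border-blob cleanup could
recover — the passing tests therefore certify robustness to realistic
correlated background variation, not to arbitrary white noise. Other real
features the generator does not emulate: out-of-focus halos, yolk
autofluorescence, touching embryos (only a border-touching neighbour is
modelled), and stain saturation.

Batch rendering derives per-embryo seeds from a master seed
(`numpy.random.SeedSequence`); output is byte-deterministic for a fixed
spec.

## Numerical choices and problem sizes

Thresholds are inclusive (`value <= t -> 0`), matching the documented
"lower or equal" semantics. The Gaussian kernel radius is the smallest
with omitted two-sided tail mass below the accuracy parameter per axis.
Knot x-coordinates must be strictly increasing; duplicate columns are an
error rather than silently perturbed. Medians use NumPy's convention
(mean of central pair for even counts). Tests run the full pipeline on
single embryos at the default 1036 x 1360 canvas and batch/store tests on
a reduced 420 x 620 canvas (semi-axes 210 x 80), which keeps the suite
fast while exercising identical code paths; segmentation quality is
asserted over 20 seeds at noise SD 0 (IoU >= 0.98) and SD 10
(IoU >= 0.95), and boundary recovery within 1 %EL noiseless / 2 %EL at
SD 10.

## Known limitations

- Segmentation assumes exactly one complete embryo not touching the image
  border; multi-embryo scenes and shape-model approaches are out of scope.
- The blur/re-threshold stage erodes high-curvature embryo tips by a few
  pixels; with frame-filling embryos this costs well under 1% IoU but it
  grows for small embryos (the `beta` caveat of the original applies:
  raise it for small species).
- A-P/D-V polarity (flips) and staging are manual inputs by design.
- Expression levels are not comparable across embryos; only boundary
  positions are meaningful outputs.
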