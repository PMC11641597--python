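# Methods

## Segmentation model

The nuclear foreground is the minimiser of the relaxed two-phase energy

    E(u) = Σ_x |∇u(x)| + λ Σ_x f(x) u(x),   u(x) ∈ [0, 1],

with fitting term f(x) = t_δ − z_δ(x), where z_δ is the DAPI channel
normalised to [0, 1] and t_δ is an Otsu threshold of its histogram. The
model assumes two intensity populations (background and nuclei) and that
nuclear interiors are brighter than everything one wants to exclude; it is a
regularised thresholding, not a shape model, so touching nuclei merge into
one region (see Limitations). An edge-weight hook g(x) multiplying the TV
term exists but is fixed to g ≡ 1: nuclear edges in fluorescence are too
diffuse for gradient weighting to help.

Because the problem is convex with u relaxed to [0, 1], the computed
solution is approximately binary and thresholding it at any β ∈ (0, 1)
yields a global minimiser of the original binary problem. The foreground is
Ω_D = {u* > β}; its 8-connected components are the nuclei.

## Discretisation and solver

Forward differences with replicate (Neumann) boundaries; isotropic gradient
magnitude √(u_x² + u_y²); the divergence is the exact negative adjoint of
the gradient. The Split Bregman scheme alternates, per outer iteration:

1. one damped Jacobi sweep of the screened-Poisson u-subproblem
   Δu = (λ/μ) f + div(d − b), followed by clipping u to [0, 1];
2. isotropic vector shrinkage d = shrink(∇u + b, 1/μ);
3. the Bregman update b ← b + ∇u − d.

The iteration starts from the indicator of {f < 0} (the plain threshold
set), which is close to the minimiser; the converged foreground is
independent of the start, which the test suite verifies by also running from
u ≡ 0. Split Bregman is not monotone in E iterate-by-iterate, so the solver
tracks and returns the lowest-energy iterate seen (the start included),
which makes E(u*) ≤ E(u₀) a hard guarantee.

Numerical choices:

- Stopping: relative change ‖u^{k+1} − u^k‖/‖u^k‖ < 1e−5, cap 200
  iterations. Typical convergence is 25–80 iterations on a 512² field
  (~1–2 s on one CPU core; a 1024² three-channel acquisition runs end to
  end in seconds). The tolerance is set one decade tighter than the point
  where we first observed a single borderline boundary pixel (u ≈ 0.5)
  landing on different sides of β for different initialisations; at 1e−5
  the two prescribed starts agree pixel-exactly on every test fixture.
- Penalty weight μ = 1 (shrinkage threshold 1/μ = 1). Convergence speed is
  insensitive to μ over 1–20 on these images.
- Hitting the iteration cap is reported (`converged=False`), logged, and is
  not an error.
- Degenerate (constant) DAPI channels cannot be Otsu-thresholded; the image
  is recorded with zero counts and flagged in the log instead of aborting a
  batch.

## Otsu thresholding

256-bin histogram between the channel minimum and maximum; the cut
maximising the between-class variance (equivalently minimising the weighted
intra-class variance). Fluorescence fields routinely have a small bright
foreground over a large uniform background, which makes the between-class
variance exactly or nearly flat across the empty histogram gap between the
two modes: every cut in the gap is an equally valid Otsu threshold. Ties
are resolved to the midpoint of the optimal plateau, which keeps t_δ well
away from both modes. Resolving ties to the first optimal bin instead (as
some library implementations do) puts the threshold immediately above the
background level, making f ≈ 0 over the whole background and promoting dim
debris above threshold. The implementation is checked against an
exhaustive-scan intra-class-variance oracle in the tests.

## Marker counting

One global Otsu threshold per marker channel per image, floored at
t_f = 0.1 on the normalised scale: t_χ = max(Otsu, 0.1), with the floor
also covering the degenerate constant-channel case. The floor exists
because Otsu is unreliable when a channel carries little or no signal; 0.1
is meaningful only because integer images are normalised by the full scale
of their bit depth (2^b − 1), not per-image min-max — per-image rescaling
would force every channel to reach 1.0 and silently change what the floor
means. A per-image min-max mode exists as an explicit option for
real-valued inputs that arrive unscaled.

Positivity is strict (z > t_χ at ≥ 1 pixel of the nucleus), binary per
nucleus, and blind to signal outside Ω_D. Raising the threshold can only
decrease a count; each count is bounded by n.

There is no minimum-object-size filter and no border-object exclusion by
default: debris bright enough to cross the threshold is counted (review via
the overlays is the intended mitigation, and an optional `min_area`
parameter exists), and nuclei cropped by the image border count like any
other.

## Concordance metrics

For one image, the raters' (DAPI, marker) integer count pairs define a
centroid (arithmetic mean; unweighted Euclidean distances on raw counts). A
counter is concordant when its distance to the centroid is strictly below
the farthest rater's distance; the percentage of concordant images is the
percentage concordance. The algorithm is scored against the centroid of all
raters while a rater under leave-one-out is scored against the remaining
raters' centroid — an asymmetry that slightly favours the algorithm and is
reproduced deliberately, matching how the published comparison defines the
metric. Strictly-below means exact ties (e.g. all counters identical) score
as non-concordant; that case is degenerate and logged. Counts outside the
rater range are summarised as a signed percentage relative to the nearest
range boundary: above-range counts relative to the rater maximum,
below-range counts relative to the minimum.

## Synthetic fields

The generator renders what the pipeline must survive, with exact ground
truth: non-overlapping elliptical nuclei (radius 6–16 px, axis ratio up to
1.4, spanning condensed to large polyploid sizes), intensity 0.75 over a
0.05 autofluorescence background with a 2 px cosine edge taper, additive
Gaussian noise (default σ = 0.02), isolated hot-pixel speckles (rate 2e−4,
value 0.5, counterstain only), a few dim detritus blobs (intensity 0.18),
and 10% of nuclei cropped by the image border. Marker foci (intensity 0.8)
are placed strictly inside a known subset of nuclei: 40% Ki67-positive
(3 foci, r = 2.5 px) and 60% γH2AX-positive (5 foci, r = 1.5 px) by
default. Marker channels carry a darker background (0.02) and a quarter of
the counterstain noise, reflecting that fluorescence noise scales with
collected signal and marker channels are black outside sparse puncta — the
0.1 floor is only meaningful under that condition. A dim preset (foci at
0.08, below the floor) exercises the floor path.

Nuclei are placed by rejection sampling with ≥ 4 px clearance, so the
ground-truth label image and the rendered pixels agree exactly. The
noiseless oracle-equivalence fixtures additionally use a zero-width taper
and no speckles/detritus: on such piecewise-constant fields the TV
minimiser coincides with the plain threshold set pixel-for-pixel, which the
tests assert exactly.

Not emulated: optical point-spread, vignetting, chromatic shift, uneven
illumination, and — deliberately — overlapping or touching nuclei. Passing
tests therefore demonstrate correctness of the algorithm under its own
assumptions, not performance on confluent cultures or poorly separated
tissue fields.

## Test problem sizes

Unit tests run on 128–256 px fields with ≤ 10 nuclei. The end-to-end suite
uses twenty noiseless 512² fields with 5–60 nuclei (seeds 1–20), fifteen
noisy 512² fields (5 replicates at σ ∈ {0.01, 0.03, 0.05}), and one 1024²
three-channel field for the runtime check; the acceptance script uses the
same sizes with seeds derived from its `--seed` argument.

## Known limitations

- Touching or overlapping nuclei merge into one Ω_D component and count as
  one nucleus; the model has no splitting mechanism (no watershed, no shape
  prior).
- The binarisation level β is immaterial on exactly piecewise-constant
  solutions, but the discrete isotropic-TV minimiser keeps a thin genuinely
  fractional band (≈ 0.06% of pixels) along soft-edged boundaries where
  f ≈ 0; foreground pixels inside that band can flip between
  β ∈ {0.25, 0.5, 0.75}. The nucleus count is unaffected on every test
  fixture; only the region outlines move by ≤ 1 px.
- A single global threshold per marker channel assumes spatially uniform
  background; strong local autofluorescence would need per-region
  thresholds, which are out of scope.
- Very dim genuine signal (below the 0.1 floor) is indistinguishable from
  background by construction and counts negative.
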