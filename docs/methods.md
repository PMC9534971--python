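# Methods

`vesselwell` quantifies fluorescence mosaics of endothelial-cell (EC) /
smooth-muscle-cell (SMC) direct-contact cocultures grown in circular wells
on an orbital shaker, and ships a synthetic scene generator with full
ground truth so that every statistic can be validated against known
parameters. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## Well geometry and flow

A well is a disk of radius R. Because the swirling flow is pulsatile and
near-tangential at the rim but disturbed and multidirectional near the
middle, every readout is reported for two annular zones split at a radial
fraction `split_fraction` (default 0.5, i.e. the middle of the radial
position): `center` is `r < 0.5 R`, `periphery` is `0.5 R <= r <= R`.
Pixels at exactly the split radius go outward — a single deterministic
tie-break. The local flow direction is the counter-clockwise tangent;
alignment statistics use unsigned angles, so the orientation convention
cannot affect any observable.

`fit_well` locates the disk in real stacks by thresholding the
max-projection (Otsu), keeping the largest connected component, and using
its centroid and equivalent-area radius. Disks touching the image border
are flagged `truncated`.

## Orbital-shaker wall shear stress

The shear magnitude is estimated with the Stokes-second-problem closed
form for an orbitally swirled dish,

    tau = r_orb * sqrt(rho * mu * omega^3),    omega = 2*pi*rpm/60,

interpreted as the cycle-peak shear at the wall away from the well center.
Defaults are the study operating point: 135 rpm, 9.5 mm orbit,
rho = 1000 kg m^-3, and mu = 7.8e-4 Pa s (DMEM-like culture medium at
37 °C; the medium viscosity is not a measured quantity here and is
config-exposed). At these values tau = 0.446 Pa. Published CFD of swirled
6-well plates gives zone-resolved mean-WSS windows (periphery 0.4–1.2 Pa,
center 0.3–0.8 Pa at 135 rpm); `zone_shear_summary` reports those windows
as annotations together with a consistency flag for the analytical value,
rather than re-deriving free-surface CFD. The analytical value is a
cycle-peak estimate and is deliberately not conflated with the CFD radial
mean. Rotation frequency maps one-to-one onto a heartbeat-equivalent rate
(one orbit = one shear pulse); the default band table labels (40, 100] bpm
resting and (100, 200] bpm exercise.

## Synthetic scenes

Each scene is a six-channel stack (EC junction+nuclear composite, SMC cell
tracker, fibronectin, DAPI, Ki-67, ERG1) of one circular well, with ground
truth: the region label map, the nucleus table, and the corrugation and
fibronectin masks.

**Scale.** Scenes are desk-scale miniatures: at the default 4 µm/px and
R = 480 px the well is ~1.9 mm in radius rather than 17.5 mm, while cell-
scale texture (EC cells ~30 µm, SMC ~40 µm, nuclei sigma 1.8 px) is to
scale. All structure sizes are set in physical units and scale with
`pixel_size_um`.

**Region label construction.** Targets are area fractions per zone for
islands and networks. Islands are the upper level set of a long-
correlation Gaussian random field, thresholded at the per-zone quantile
that meets the target exactly; the binary set is then regularized
(Gaussian smoothing of the indicator and re-thresholding at the same
quantile), which removes sub-cellular arms and necks — confluent patches
are compact — while preserving the fraction to pixel resolution. Networks
are webs of constant-width cords: bands of half-width 5.5 px (~11 px ≈ 1.5
EC cell diameters wide) around level sets of a shorter-correlation field,
using the first-order distance `|f - c| / |grad f|`; levels are added
around the median until the target pixel count is reached and the last
level is truncated at the exact count. Fractions therefore match the
configuration to a few pixels for any seed (tested at ±0.03).

**Rendering.** Island cobblestone is drawn as Voronoi borders (bright
membranes over a dimmer interior) from cell centers placed by minimum-
separation sampling; those centers double as the EC island nuclei. Under
shear the peripheral island texture is multiplied by a tangentially
elongated random field (noise laid out on an (r, θ) grid, smoothed along
θ, mapped back), which encodes flow alignment as an oriented intensity
component rather than geometric cell elongation — sufficient for
structure-tensor readouts, and a stated simplification. Corrugated SMC
ridges (the in-vitro analog of intimal thickening) are the upper quantile
of an oriented field restricted to defected (gap + network) area, covering
`corrugation_coverage` (default 0.85) of it; the SMC channel is the base
level times `corrugation_multiplier` (default 2.5) on ridges, so the
expected gap layering index is 1 + coverage × (multiplier − 1) ≈ 2.3.
Fibronectin fibers are thin level-set bands restricted to defects with
intensity proportional to the local SMC signal. Nuclei are Gaussian spots;
SMC nuclei cover the whole well (the SMC layer sits below the endothelium)
with a small lateral clearance from EC nuclei so that the projected image
remains resolvable, and extra nuclei are added on ridges (multilayering).
Proliferation flags are Bernoulli draws with per-(zone, class) rates for
SMC nuclei and a scalar EC rate.

**Noise.** Per-tile multiplicative vignetting on a square grid (stitching
pattern), then Poisson shot noise (`poisson_scale` photons per count),
then additive Gaussian read noise, over a constant background. One seeded
RNG per scene, with per-stage substreams derived via `SeedSequence.spawn`;
identical configurations are bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real VE-cadherin junction morphology and
single-cell shape, z-structure (everything is a 2-D projection),
photobleaching and stage drift, uneven illumination beyond the tile grid,
segmentation-relevant debris/artifacts, and any biological coupling beyond
the configured rates (the generator realizes configured statistics; it has
no dynamics).

## Texture segmentation

Binarization: Gaussian smoothing (0.5 px), Otsu threshold over in-well
pixels, closing (radius 1), small-hole filling, speckle removal. Two
guards make the Otsu split safe at the extremes: if the foreground class
is statistically indistinguishable from the outside-well background the
mask is empty (blank channel), and if the *below*-threshold class median
sits far above background the well is nearly confluent — Otsu has split
two signal textures — and a background-referenced threshold
(median + 6 robust SD of outside-well pixels) is used instead. With Otsu
the mask is invariant to a constant offset.

Classification into island / network / gap rests on an EC-thickness
feature: the distance transform of the EC mask. Network cords are at most
1–2 cell diameters wide, so cord pixels never lie deeper than
`cord_halfwidth_px` (default 12) inside the foreground, while island
bodies reach `island_min_halfwidth_px` (default 18) and beyond. Islands
are recovered by hysteresis — connected components of
`depth >= cord_halfwidth_px` that contain an island-deep seed — and the
rim eroded by that criterion is reclaimed by dilation gated with a
local-coverage density feature (window 31 px, minimum 0.5), so cords
touching an island are not swallowed. Remaining EC pixels are network;
EC-negative in-well pixels are gap. Components smaller than
`min_object_px` merge into their surrounding class; island candidates
without a deep core are demoted if their skeleton-based elongation is
cord-like (this guards the degenerate fallback, where a well with no
island-deep seed is assigned entirely to one EC phase by overall
coverage). An earlier pure sliding-window density classifier was
boundary-limited (the window mixes phases over its own width); the
thickness criterion is boundary-accurate, which is what the ≥0.85
per-class Jaccard requirement needs. Defaults were calibrated against the
generator's default textures with `calibrate_params` (deterministic grid
search maximizing mean per-class Jaccard); on fresh scenes they achieve
island ≈0.91–0.96, network ≈0.85–0.88, gap ≈0.94.

Flow alignment: the structure tensor (sigma 3 px) gives the local texture
orientation; the order parameter is the mean of cos(2Δθ) between structure
orientation and the local tangent over island pixels, after eroding the
island mask by twice the tensor scale (boundary gradients carry no
orientation information about the texture) and excluding the band at the
well rim, whose circular edge would read as spurious tangential alignment.
1 = tangentially aligned, 0 = isotropic. Zones without usable island
pixels report NaN.

## Region statistics

* **Coverage**: class pixels / zone pixels; the three fractions sum to 1
  per zone by the partition property; total EC = island + network (the
  default reading of "total coverage"; the binarized-EC-area alternative
  is a one-liner on the mask). Optional equal annular-sector ROIs (default
  8 per zone) expose local variance.
* **Nuclei**: local maxima of the smoothed DAPI channel above a robust
  background threshold (median + 6 MAD of outside-well pixels) with a
  3 px minimum separation. Identity (ERG1) and proliferation (Ki-67)
  flags are read at the peak pixel of the smoothed marker channel against
  a 10-MAD robust threshold: a disk-mean readout leaks neighboring EC
  nuclear signal in crowded cocultures, the peak-pixel readout does not.
  Nuclei are assigned to zone and region class by their centroid pixel —
  simple, deterministic point statistics.
* **Proliferation**: % Ki-67+ among ERG1-negative (SMC) nuclei per
  (zone, class); cells with fewer than `n_min = 20` SMC nuclei are
  reported missing, not zero (no such floor is inherent to the data; it
  guards unstable small-n ratios).
* **Layering index**: mean background-subtracted cell-tracker intensity
  over class pixels divided by the island mean of the same zone, so the
  single-layer reference is exactly 1 per zone. Background is the median
  of outside-well pixels. The index is invariant to global gain. If a
  zone has no island pixels the whole-well mean is used and flagged.
* **Radial profiles**: annular bins from rim to center; per bin, mean SMC
  and Fn intensities min-max rescaled to 0–255 across the profile (the
  plotted convention), class occupancy fractions, and Fn/SMC computed on
  raw background-subtracted values (mixing the rescaled values into the
  ratio would break gain invariance); the ratio is undefined where SMC is
  below a floor.
* **Group comparison**: one-way ANOVA (scipy) followed by Tukey's HSD
  (statsmodels) with family-wise adjusted p per contrast. Significance
  stars follow the source material's printed thresholds
  (**** < 0.001, *** < 0.01, ** < 0.1, * < 0.5) and are config-exposed,
  since that mapping is unusual. All-constant input is reported as
  degenerate rather than producing a spurious statistic.

## Fixtures and problem sizes

The validation fixture set spans {quiescent, IH low-density, high-density}
× {shear, static} with effect sizes large enough that pipeline recovery is
unambiguous at desk scale (proliferation 5% under islands vs 25–30% in
defects; corrugation multiplier 2.5 vs 1.0; island fraction shifted
+0.15 / network −0.15 between shear and static). Default problem sizes:
unit tests run 384–768 px scenes; the segmentation recovery check runs
five 1024 px scenes; the proliferation recovery check runs one 1792 px
scene with 16 µm SMC cells so that every (zone × class) cell holds at
least 2000 SMC nuclei (binomial 3-SD bounds are then ~1–2 percentage
points). The whole suite completes in a few minutes on one CPU.

## Known limitations

The segmentation defaults assume the generator's texture scales (cords
~1.5 cell diameters, islands several cells wide at 4 µm/px); other
magnifications need `calibrate_params` or rescaled parameters. The
thickness criterion cannot subdivide an island-sized solid patch of
genuinely cord-phase cells, and narrow straits between touching islands
may be bridged or cut at the `cord_halfwidth_px` scale. Nucleus detection
degrades gracefully but measurably above ~70% of the packing density.
The shear model is a single closed-form operating-point estimate, not a
radially resolved WSS field.
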