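# Methods

`meptrace` quantifies how well an intramuscular tracer injection covers the
motor-endplate (MEP) region of a muscle, and how many spinal motor neurons
the injection retrogradely labels.  Because raw imaging data of this kind
are rarely deposited, the package pairs the quantification pipeline with a
synthetic-scene generator that carries full ground truth, so every stage is
verifiable end to end.  This note documents the models, the defaults and
their rationale, the numerical choices, and what the synthetic scenes do
and do not establish about real data.

## Coordinate conventions

All physical coordinates are continuous, in μm.  Muscle grids use axis
order (depth, row, col): axis 0 points from the superficial surface into
the muscle, axis 1 runs rostro-caudally (proximo-distally), axis 2
medio-laterally.  Spinal-cord stacks use axis 0 = rostro-caudal (R–C),
axis 1 = medio-lateral (M–L), axis 2 = ventro-dorsal (V–D).  A continuous
coordinate maps to a voxel by `floor(coord / voxel_size)`; "injection
depth" is measured from the most superficial voxel of the muscle mask.
Each generator takes a single integer seed and draws all of its randomness
from one `numpy` generator instance, so every output is a pure function of
(parameters, seed).

## Synthetic muscle scenes

**Muscle volume.** An axis-aligned ellipsoid, the simplest smooth connected
volume consistent with the silhouettes of the two muscles modelled.
Defaults: gastrocnemius semi-axes (1.3, 4.0, 2.5) mm, tibialis anterior
(0.85, 3.0, 1.25) mm, both at 50-μm voxels — mouse-hindlimb scale, coarse
enough that a full scene renders in well under a second.

**Endplate distributions.** Endplates in these muscles form thin lamellar
structures, and the package stylizes the two published shapes:

- *M-sheet* (gastrocnemius): a sheet of half-thickness 240 μm (Gaussian
  σ = 120 μm, hard-truncated at 2σ) that is **oblique** to the muscle
  surface — 0.8 mm deep at its rostral edge, gaining 0.4 μm of depth per μm
  of row over a 3-mm band, so most of its mass sits near 1.4 mm depth.
  Across the medio-lateral axis the mass is concentrated in two humps
  (Gaussian weights at ±0.55 of the col scale, base weight 0.3), the legs
  of the "M" seen from above.
- *Triangular pyramid* (tibialis anterior): three oblique planar faces
  (azimuths 0°, 135°, 225°) rising from a deep apex at 1.4 mm to shallow
  ends at 0.65 mm, widening from 100 to 600 μm half-width, plus an explicit
  apex cluster holding 30 % of the mass where the faces meet.

The density is clipped to the muscle mask and normalized to 1; endplate
points are i.i.d. samples from it (voxel choice + uniform jitter within the
voxel), so containment in the mask holds by construction.  The obliquity of
the M-sheet is the load-bearing modelling choice: it encodes the premise
that the endplate band visible **on the muscle surface** is a biased,
depth-blind picture of the interior distribution.  No quantitative
parameterization of these shapes has been published; the parameters are
exposed (`MSheetParams`, `PyramidParams`) and the defaults were fixed once
on anatomical plausibility.

**Injection strategies.** Both strategies inject 500 nl per site and match
the published per-muscle site counts, depth windows and total volumes
(gastrocnemius: 7 sites at 1.2–1.5 mm, 3.5 μl; tibialis anterior: 4 sites,
2.0 μl, with the 3D variant placing three at 0.6–0.8 mm and one deep at
1.3–1.5 mm and the 2D variant all four at 0.6–0.8 mm).

- *3D placement* targets the volumetric density: candidate voxels are
  restricted to the tabulated depth window(s) and sites are picked greedily
  by descending density with a minimum separation (800 μm gastrocnemius,
  600 μm tibialis anterior; ties broken by flat voxel index, so placement
  is deterministic).
- *2D placement* targets the **surface-visible** band: the density is
  projected with exponential depth attenuation (length constant 250 μm,
  the scale over which surface staining or illumination fades), and sites
  are greedy maxima of that projection at the mid-point of the tabulated
  depth range.

With these two rules the strategies differ exactly where they differ in
practice: the 2D plan lands on the shallow rostral edge of the
gastrocnemius sheet and misses its deep caudal mass, and never reaches the
tibialis anterior apex.

**Tracer diffusion.** Each site contributes an isotropic Gaussian of
standard deviation `400 μm × (volume/500 nl)^{1/3}` (volume-proportional
spread; 400 μm per 500 nl is order-of-magnitude consistent with mm-scale
diffusion footprints in sectioned muscle).  Mass falling outside the mask
is clipped and the remainder renormalized into the mask: fascia is treated
as reflecting, not absorbing, so total mass stays proportional to injected
volume.  The model is phenomenological — it reproduces containment and
volume scaling, not poroelastic transport.

**Section rendering.** Sections are 60-μm maximum-intensity slabs, the
standard projection thickness for this preparation.  The tracer channel
projects the diffusion field (scaled to peak 200); the endplate channel
renders each in-slab point as a Gaussian punctum (σ = 60 μm, peak 160 above
background) **truncated at half-maximum**, so the noise-free support of the
channel equals its ground-truth mask exactly.  Autofluorescence is modelled
as a constant background (30) plus Gaussian noise (SD 6) and sparse impulse
noise (density 5 × 10⁻⁴, amplitude 300) — the impulse component is what the
median prefilter in the segmentation stage exists to remove.  The tracer
truth mask is the half-maximum threshold of the noise-free projection.

**Cord scenes.** Labeled motor neurons form one longitudinal pool; the
generator samples centroids uniformly in a box of per-axis extents
(2,200, 260, 190) μm — the scale of a mouse gastrocnemius pool — with a
minimum separation of one soma diameter (rejection sampling; an error is
raised if the pool cannot hold the requested count).  Somata are 3D
Gaussian blobs (diameter 20 μm, σ = diameter/4, evaluated within 3σ) of
peak intensity 100 over Gaussian background (mean 10, SD 10 → SNR 10 by
default), at 5-μm isotropic voxels matching the axial step of cleared-cord
light-sheet stacks.

## Coverage quantification

Per section: the tracer channel is binarized (Otsu by default, manual
override available, mirroring per-image manual thresholding practice) and
holes are filled — every background component not 4-connected to the image
border becomes foreground, which removes the dark cores that heterogeneous
tracer fluorescence leaves inside the diffusion region.  The endplate
channel is median-filtered (3×3 by default; the filter type/size is
configurable, median chosen because the dominant nuisance is impulse-like
autofluorescence) and binarized, with no hole filling.  Coverage is
`|MEP ∧ CTB| / |MEP|`, computed by mask multiplication and pixel counting;
the mean over sections is unweighted.  An empty endplate mask makes
coverage *undefined* — the implementation raises (or, in profile
aggregation, records NaN and excludes the section with a warning) rather
than reporting 0, which would fake "no coverage" where there is no signal.
Mask inversion for display is provided but provably cannot change any
count.  In strategy comparisons the endplate threshold is a fixed manual
value (80, between background and punctum peak) identical across
strategies, so the comparison is never confounded by adaptive thresholding.

## Neuron detection

An open reimplementation of the closed-source "Spot" workflow, specified by
its recovery contract rather than by mimicking internals: Gaussian
smoothing with σ = diameter/4 per axis; candidate spots are neighbourhood
maxima of the smoothed volume above threshold; conflicts within the minimum
separation (default one diameter) keep the brighter candidate, ties broken
by smaller flat voxel index, making detection deterministic; sub-voxel
centroids are intensity-weighted centroids of the smoothed volume in a
diameter-sized window.  The default threshold is background-relative:
median + 8 robust SDs (1.4826 × MAD) of the smoothed volume.  Eight is
deliberate: smoothing leaves a soma of raw SNR 5 about 12 robust SDs above
the smoothed background while white noise in a multi-megavoxel stack
produces excursions near 5–6 SDs, so 8 sits in the wide gap between the
two.  Pool extents are per-axis max−min by default ("range" in the
reporting convention of this literature) with a 1st–99th percentile
alternative, since the commercial statistic is not documented.

## Group comparison

The gated flow used in this literature (as implemented in SPSS):
Shapiro–Wilk per group; if either p < α the two-sided Mann–Whitney U-test
is used (exact enumeration when a group has n < 8 and there are no ties,
tie-corrected normal approximation otherwise — n = 4 groups demand
exactness); otherwise Levene's test (mean-centred, the classic SPSS form)
routes to the pooled-variance or separate-variance (Welch) t-test.  Gate
α = 0.05 per group (unstated in the source convention; conventional choice,
documented here).  A zero-variance group, where Shapiro–Wilk is undefined,
routes to Mann–Whitney with a warning.  Summaries are mean ± SEM
(SD with n−1 denominator over √n); percent improvement is
100 × (new − ref)/ref rounded half away from zero to 2 decimals.  Under a
simulated null (normal, equal means, n = 8 per group — large enough for
stable gates, small enough to be realistic) the full adaptive procedure
rejects at ≈ 5 %, which the acceptance script recomputes.

## Pipeline linkage

The umbrella pipeline connects the two halves with a deliberately simple
labeling model: the number of retrogradely labeled neurons is
`round(pool_size × mean_coverage)` (default pool 220).  This encodes the
mechanism under study — tracer uptake happens at endplates, so labeling
scales with endplate coverage — without claiming a quantitative
dose–response.  Reruns with identical config and seeds are bit-identical;
the summary JSON carries a config hash and every threshold actually used is
logged.

## Problem sizes and numerical choices

Default scenes (≈ 1 M voxels per muscle, ≈ 2.3 M per cord stack, 3–4
sections per muscle, 3,000/1,500 endplate points) were chosen so that a
20-seed strategy comparison runs in seconds on one core while keeping the
tracer spread, sheet thickness and soma size several voxels wide.  The
seed-independent parts of a scene (density, plan, tracer field) are cached
per (muscle, strategy).  Degenerate inputs are handled explicitly: constant
images have no Otsu threshold and yield empty masks with a warning; empty
spot sets have no extent; sites outside the mask and depths outside the
volume raise.

## What the synthetic scenes do not show

The generator reproduces the *structure* of the experiment — lamellar
endplate geometry, depth-blind surface guidance, fascia containment,
slab-projected two-channel sections, a bright-somata pool — not real
anatomy: no fiber architecture, no photon-level optics, no spectral
bleed-through, no tissue deformation between sections, and a
phenomenological diffusion model.  Passing tests therefore establish that
the quantification is correct and that the 3D-over-2D ordering follows
from depth-structured endplate distributions; they do not predict the
numerical coverage or neuron counts of any real muscle.  Published
real-data values (mean coverages, counts of 183 vs 109 neurons, pool
extents) depend on undeposited images; the package reproduces the worked
arithmetic on the printed group means (e.g. the 67.89 % improvement) and
the qualitative orderings, nothing more.
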