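# Methods

This note documents the models, parameter choices and numerical conventions
behind `metalloscope`, and what the synthetic tests do and do not establish
about real correlative STED/SXRF data.

## Coordinate frames and registration

All positions are physical nanometres with the origin at the top-left pixel
centre, x rightward along columns, y downward along rows; pixel (i, j) is
centred at (j·a, i·a) for pixel size a. The optical and synchrotron
instruments each record positions relative to three labelled corners of the
silicon-nitride frame. Three matched non-collinear point pairs determine a
planar affine transform exactly (six equations, six unknowns), so
`fit_affine_from_fiducials` solves the 3×3 linear system directly rather
than least-squares fitting a constrained similarity: the extra shear degree
of freedom absorbs stage-axis non-orthogonality, and a negative determinant
identifies the mirrored view that arises when the two instruments image
opposite faces of the membrane. Fiducial triangles with area below 10⁻⁶ nm²
are rejected as degenerate. Fine refinement (`refine_by_correlation`) is
deliberately translation-only: it scans integer-pixel shifts within a search
radius, maximizing the masked Pearson correlation, with an optional
parabolic sub-pixel peak fit (~0.1 px). Rotation/scale refinement and
deformable models are out of scope — structure-based manual alignment of
this kind of data is, in practice, a small residual translation.
Resampling uses inverse mapping with bilinear interpolation; destination
pixels mapping outside the source are flagged missing (NaN), never
zero-filled, and stay excluded from all downstream statistics.

## XRF unit conversions and detection limits

Quantified XRF maps arrive as areal mass density σ in ng/mm². With pixel
side a (nm), molar mass M (IUPAC 2021 standard atomic weights, one shared
table) and Avogadro's number N_A:

- per-pixel mass m = σ·10⁻²¹·a² g (1 ng/mm² ≡ 10⁻²¹ g/nm²);
- atomic density n = σ·10⁻²¹·N_A/M atoms/nm².

Conversions are linear and carried at full precision; rounding to two
significant figures happens only in reports. The detection limit follows
the IUPAC convention LOD = m_b + k·σ_b with k = 3, where m_b and σ_b are
the mean and *sample* (n−1) standard deviation of replicate blank
measurements (at least two required). Note that when published areal LODs
are themselves rounded to three decimals, atom counts recomputed from them
can land one step away from the originally published two-significant-figure
values; this is a property of the rounding, not of the conversion.

## Background estimation and colocalization

When no explicit blank region is supplied, background statistics come from
kappa-sigma clipping: starting from all pixels, iterate (mean, SD, drop
pixels above mean + k·SD) until the set is stable or 50 iterations (then a
warning is raised and the last iterate returned). The foreground threshold
is the background mean plus k = 3 standard deviations **of the background
pixel values** — using the standard error of the mean instead would put the
threshold a fraction of a count above the mean and exclude nothing.
Pearson correlation between two channels is computed over the union
(default) or intersection of the per-channel foreground masks; the union is
the default because correlating only jointly-bright pixels biases r upward.
At least three pixels and non-zero variance in both channels are required.
Line profiles sample a polyline at one-pixel arc-length steps with bilinear
interpolation, averaging perpendicular to the local direction over the
requested width; min-max normalization of a constant profile is undefined
and returns zeros with a warning.

## Stoichiometry

The S/metal atomic ratio of a region of interest is the ratio of
background-corrected mean atomic densities over the ROI (means, not sums,
so the ratio is independent of ROI size). Background correction defaults on
and subtracts each map's kappa-sigma background mean — on synthetic scenes
this removes the additive blank level and makes the recovery unbiased. ROIs
whose corrected denominator is not positive are excluded with a logged
reason. Ratios aggregate as arithmetic mean ± sample SD over ROIs. Protein
molecules per metal atom is the ratio divided by the protein's sulfur
content (Met + Cys residues counted from sequence, 49 for the tubulin-αβ
dimer); because the divisor is an exact constant, the SD scales by the same
factor (no delta-method propagation is needed). The result is a
*colocalization* stoichiometry: pixels record co-occurrence at 40 nm scale,
not chemical binding. The bundled FASTA
(`tests/data/synthetic_tubulin_dimer.fasta`) is a synthetic stand-in with
the correct sulfur composition (24 + 25 = 49 M+C over two chains), not a
database sequence.

## Fluorescence group comparison

Per image, the segmentation threshold is the lower edge of the histogram
bin immediately above the modal bin (256 equal-width bins over the observed
range by default, the 8-bit convention of the acquisition software; ties on
the modal count break toward the lowest bin). This estimator assumes the
dominant mode is a background narrow relative to the bin width — exactly
the regime of the targeted images; with a broad background it over-segments
(the tests exercise the narrow regime). Somas are excluded by mask, and the
mean foreground intensity (counts/pixel) per image is the unit of analysis;
images with empty foreground are excluded and counted, never imputed.
Intensities are normalized by the control-group median, per biological
replicate when replicate ids are present.

The comparison follows a fixed decision tree: Shapiro-Wilk per group and
Bartlett across groups at alpha 0.05 (the customary level; the report
records it); two groups → Student t-test if both gates pass, else
Mann-Whitney U; three or more → one-way ANOVA with Tukey HSD if both pass,
else Kruskal-Wallis, followed by Dunn's rank test with Holm adjustment only
when the omnibus p is below the 0.01 gate. Dunn's z uses the tie-corrected
variance N(N+1)/12 − Σ(t³−t)/(12(N−1)). Tukey comes from scipy; Dunn is
implemented here (no standard package in the dependency set provides it)
and is validated against a hand-computed no-tie example. The report records
every gate outcome and the exact path taken.

## Synthetic scenes: what they emulate

The generator draws dendrites as smooth random-heading polylines leaving a
soma, rasterized one pixel wide as tubulin filaments; spines are
stalk-plus-head structures with heads 300–800 nm across, attached along
dendrites. Element truth is constructed so the analysis has exact targets:
S = 49 × tubulin dimer density on filaments plus a diffuse non-tubulin
sulfur background over the *off-filament* cell area (keeping the
pure-filament S:Zn ratio exactly 49:1 by construction); Zn = σ × tubulin
with σ = 1 dimer⁻¹ (optional spine hot spots, off by default); Cu sits in
Gaussian spots at spine bases where F-actin is densest; P covers the cell
mask. Tubulin density is modulated ±30% along each filament by a smoothed
random walk — without spatial variation of the true signal a masked Pearson
coefficient would measure only noise, which no real image does.

Rendering converts atoms/nm² to ng/mm², blurs with the 40 nm beam PSF
(reflective boundaries, so total atom counts are conserved exactly), adds a
per-element blank level (set to one third of the detection limit so blanks
sit below LOD; the Cu blank equals Zn's, both being comparable trace
levels), and optionally draws per-pixel photon counts from a Poisson law
with a single counts-per-atom sensitivity — the simplest model consistent
with XRF counting statistics. Protein images are the density grids
convolved with isotropic Gaussians at the STED (40 nm FWHM, 25 nm pixels)
or confocal (194 nm FWHM, 40 nm pixels) resolution.

Default levels: 0.2 dimers/nm² on filaments puts zinc at ≈0.2 atoms/nm²,
about 2.4× its detection limit — the regime of dendritic zinc that is
clearly detectable, as in the data the analysis targets. Grouped
fluorescence images draw per-image mean intensities from a lognormal law
scaled by the treatment effect; the image-level dispersion (σ_log = 0.30,
CV ≈ 31%) is calibrated so that a 30% decrease at n = 60 images/group is
detected with adjusted p < 0.001 in ≈99% of replicates, consistent with the
highly significant outcomes such experiments report; larger dispersions
would contradict them.

What passing tests show — unit conversions, the LOD formula, the exactness
of 3-point affine recovery, unbiased ratio recovery under Poisson noise,
and the operating characteristics of the decision tree — transfers directly
to real data, because those are properties of the algorithms. What they do
not show: robustness to freeze-drying distortion (the synthetic inter-frame
transform is exactly affine), to spectral fitting artefacts in upstream
quantification, to structured (non-Poisson) detector noise, or to somas and
debris that violate the background model. 3-D structure, spectral
simulation and phase-contrast imaging are out of scope.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; identical configuration and
seed reproduce outputs bit for bit, and the pipeline writes its full
configuration plus a per-stage content hash into each run directory
(unchanged stages are skipped on rerun). Default problem sizes — 256×256 px
scenes, 21 ROIs, 12 blanks, 100–200 simulation replicates for power and
type-I checks — were chosen to mirror the scale of the targeted experiments
while keeping a full run in the seconds-to-minutes range.
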