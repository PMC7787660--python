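# metalloscope

Quantitative analysis for **correlative STED / synchrotron X-ray fluorescence
(SXRF) nano-imaging** of trace metals and cytoskeletal proteins in neurons.

Correlating super-resolution optical microscopy of proteins (STED, ~40 nm)
with synchrotron XRF maps of elements (also ~40 nm) makes it possible to ask
*which protein a metal rides on* inside a dendrite. This package implements
the computational half of that experiment:

- **Registration** of the optical and synchrotron coordinate frames from
  three labelled reference corners of the silicon-nitride support: three
  matched non-collinear points determine a planar affine transform exactly
  (a negative determinant flags the mirrored view of the membrane), with
  optional translation refinement by normalized cross-correlation on
  intra-specimen structure.
- **XRF quantification**: conversions between areal mass density σ
  (ng/mm², the native unit of quantified XRF maps), per-pixel mass
  m = σ·a² and atom count n = σ·a²·N_A/M for pixel side a and molar mass M,
  and the IUPAC detection limit **LOD = m_b + k·σ_b** (k = 3) from replicate
  blank measurements.
- **Colocalization**: background estimation by kappa-sigma clipping,
  foreground masks at mean + 3 SD of the background pixels, and Pearson
  correlation between element/protein channels restricted to foreground.
- **Stoichiometry**: per-ROI atomic ratios (e.g. S/Zn) from
  background-corrected mean atomic densities, aggregated as mean ± SD, and
  converted to a protein-molecules-per-metal ratio by the protein's sulfur
  content counted from sequence (one S atom per Met/Cys residue — the
  tubulin-αβ dimer carries 49).
- **Fluorescence group comparison** for chelation experiments:
  histogram-mode thresholding, soma exclusion, control-median
  normalization, and a fixed decision tree (Shapiro-Wilk + Bartlett gates;
  t-test/Mann-Whitney for two groups; ANOVA + Tukey or
  Kruskal-Wallis + Dunn-Holm for three).
- **Optics**: closed-form confocal (Δd = 0.4λ/NA) and STED
  (Δd = 0.5λ/(NA·√(1+ζ))) lateral resolution.
- **Synthetic scenes** with exact ground truth — dendrites, spines,
  stoichiometric Zn–tubulin coupling, Cu–F-actin co-segregation, Poisson
  counting noise, corner fiducials and an inter-frame similarity/mirror
  transform — so every stage is testable without synchrotron data.

## Worked example

```bash
metalloscope demo -o demo_run --seed 0
```

runs the full pipeline on a synthetic scene (256×256 px, 40 nm pixels,
ground-truth 1 Zn per tubulin dimer) and prints:

```
run complete in demo_run/
S/Zn = 49.0 ± 1.4 (n=21) -> 1.0 ± 0.0 dimers per Zn
```

i.e. over 21 regions of interest centred on microtubule stretches the
measured sulfur-to-zinc atomic ratio recovers the construction value 49,
and dividing by the dimer's 49 sulfur atoms returns the true stoichiometry
of one dimer per zinc atom. The run directory contains, among others:

- `lod_table.csv` — detection limits from 12 simulated blanks (for this
  seed, Zn: LOD 0.0040 ng/mm², 6.4×10⁻²¹ g ≈ 59 atoms per 40 nm pixel);
- `registration.json` — fiducial residual 0.0 nm, mirror correctly detected;
- `coloc.json` — masked Pearson matrix (this seed: r(S,Zn) = 0.996,
  r(P,S) = 0.972, r(P,Zn) = 0.733), reflecting the built-in Zn–tubulin
  coupling;
- `fluor.json` — the chelation comparison on 20 images/group with a
  simulated 30% decrease: Kruskal-Wallis p = 0.0024, Dunn-Holm adjusted
  p = 0.0016 for treated vs control, rescued vs control not significant.

The same analyses are available as a library (`metalloscope.xrf_quant`,
`.registration`, `.colocalization`, `.stoichiometry`, `.fluor_quant`,
`.optics_calc`, `.synthetic_scene`, `.pipeline`) and as focused CLI
sub-commands (`metalloscope register fit/apply`, `lod`, `atoms`, `pearson`,
`optics`, `run`).

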