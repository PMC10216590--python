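# Methods

## Optical model

The imaging target is modelled as a planar multilayer illuminated from air:
stained section (top), optional metal coating, polycarbonate carrier tape,
conductive carbon tape, silicon wafer (semi-infinite substrate).  All media
are isotropic and non-magnetic; interfaces are ideally flat (no roughness
or scattering model).  The complex refractive index convention is
ñ = n + i·k with k > 0 meaning absorption; material dispersion is tabulated
(wavelength, n, k) and linearly interpolated, with no extrapolation outside
a material's sampled range.

Reflectance/transmittance are computed with the characteristic-matrix
(transfer-matrix) method.  Internally the matrices are evaluated in the
n − i·k (Macleod) convention — the convention the standard matrix form
assumes — by conjugating the library indices; R and T are convention-
independent.  Branch cuts are chosen so waves decay into absorbing media.
The published matrix form with n + i·k fed in directly would make absorbing
layers amplify; this is the single most important numerical correctness
detail in the engine and is pinned by the independent oracle (below).

**Incoherent layers.**  The 50 µm tape and the carbon tape exceed the
coherence length of an LED, so their interference fringes are not observed.
Such layers are flagged incoherent and handled by averaging the fully
coherent reflectance over a uniform phase offset of the layer, using 64
equally spaced midpoint samples per period.  For a single slab this
reproduces the textbook incoherent-summation formula to better than 1e−6
(the equally spaced average of a smooth periodic function converges
geometrically).  Layers whose one-way attenuation exceeds e⁻¹⁰ are skipped
in the averaging (the back-reflection is annihilated, so their phase is
irrelevant); layers with |Im δ| > 300 are treated as fully opaque — the
characteristic matrix would overflow, and the transmitted intensity
(< e⁻⁶⁰⁰) is set to 0.  Both cutoffs are exact at double precision.  A
zero-thickness layer is a no-op regardless of its coherence flag.

**Independent oracle.**  `reflectance_recursive` recomputes coherent-stack
reflectance by bottom-up Parratt recursion of interface Fresnel amplitudes
written in normal-wavevector (k_z) form, sharing no code with the matrix
path.  The two engines agree to ≤ 1e−9 on randomized absorbing stacks at
oblique incidence (observed: ~1e−15).

**Band and aperture averaging.**  A source band is averaged with Gaussian
weights of the stated FWHM on 17 equally spaced wavelength nodes truncated
at ±2 FWHM; an illumination cone (numerical aperture NA) is averaged with
solid-angle weights sin θ cos θ on 8 Gauss–Legendre nodes up to asin(NA),
about normal incidence.  Both collapse exactly to the single-point
evaluation at FWHM = NA = 0.

## Contrast and configuration sweeps

Contrast between the cell and surround stacks is the ratio of brighter to
darker reflectance, C = max/min ≥ 1 (Michelson (hi−lo)/(hi+lo) is available
as an option).  The ratio form matches the magnitude scale of reported
optimum-contrast tables in this imaging mode and is symmetric under role
swap.

Default sweep grids: section thickness 10–300 nm and coating thickness
10–400 nm, both in 5 nm steps; wavelengths 390/470/555/630 nm (the LED
lines of the reference microscope).  **Sweeps default to an LED band of
25 nm FWHM** rather than a strictly monochromatic line: physical LED lines
have widths of this order, and with truly monochromatic light the ratio
contrast is unbounded wherever a reflectance crosses zero, so the grid
argmax would sit on accidental interference nulls and move chaotically with
grid step.  Band averaging is therefore both more physical and what makes
"optimal configuration" a well-posed question.  The per-material report
lists, per wavelength, the grid optimum and the smallest coating thickness
whose best-over-section contrast reaches 95 % of it (the parenthetical
convention of optimum-contrast tables).

The oscillation period of contrast versus section thickness is estimated
from the mean spacing of local maxima (prominence ≥ 5 % of the trace's
peak-to-peak amplitude, parabolic sub-sample refinement); at least two
detected peaks are required.  For a lossless section of index n on an
opaque substrate at normal incidence the period is λ/(2n); the estimate on
a damped ratio trace carries a small systematic bias (≲ 1.5 %), within one
5 nm grid step of theory at all four LED lines.

## Bundled material library

Metal and silicon entries are standard published dispersion values
(Johnson & Christy-type tables for Ag/Cu/Cr, ellipsometric handbook values
for Si), sampled at round wavelengths over 330–700 nm so that ±2 FWHM bands
around 390 and 630 nm stay in range.  Stained tissue (n ≈ 1.55, k = 0.10),
stained cell (n ≈ 1.57, k = 0.22), their poststained variants (k = 0.14 /
0.30), resin and carbon tape are synthetic placeholders — measured optical
constants for these media are not publicly available — chosen to represent
heavily OsO₄/uranyl/lead-stained epoxy sections (strongly absorbing, with
cell bodies carrying roughly double the stain density of neuropil) and
marked as such in their provenance notes.  With these constants the model
reproduces the qualitative behaviour reported for the real system (silver
the strongest contrast enhancer in the blue-violet; copper's optimum rising
steeply toward red as its reflectivity rises above the interband edge;
chromium comparatively poor), but absolute contrast values depend directly
on the placeholder k's and are not a numerical reproduction of any measured
table.  All entries are overridable from user CSV/JSON files.

## Synthetic phantoms

The phantom emulates a light-microscope-scale block of cortex: a label
volume over {neuropil, cytoplasm, nucleus, nucleolus, vessel_lumen}.
Somata (spheres, diameter 5–20 µm by default) are placed by seeded
rejection sampling with no mutual overlap; each contains one concentric
nucleus (radius fraction 0.7) and 1–3 nucleoli; vessels are straight tubes
crossing the volume; neurite processes are persistent random-walk tubes
from soma surfaces, painted over neuropil only.  The voxel grid may be
anisotropic (default 200×200×60 nm) so that 60 nm serial sections align
with voxel layers.  Default field 350×350 µm with 120 somata; the test and
demo configurations use smaller fields (e.g. 60×60×1.5 µm, 60 somata) so
the full pipeline runs in seconds on one CPU.

Sectioning takes the majority label per pixel across the slab; ties go to
the deeper/denser structure (nucleolus > nucleus > cytoplasm >
vessel_lumen > neuropil).  Majority labelling keeps the ground truth crisp
for metric tests; a thickness-weighted optical mixing of constants within
the slab would be more realistic but would blur the ground truth and is
not implemented.

Rendering maps each label to a section material (defaults: neuropil →
stained_tissue; cytoplasm/nucleus/nucleolus → stained_cell; vessel lumen →
resin), computes the stack reflectance once per label, and sets intensity
I = gain·R + offset with optional seeded Poisson and Gaussian noise.  The
defect injector overlays the artifacts seen on real coated tape: dark
scratches (straight, width ~3 px, intensity −0.3), bright jagged cracks
(+0.4) and dark specks (set to 0.05), all seeded and recorded in a defect
mask.

What the phantom does **not** emulate: within-class stain variability
(exposed as future per-label jitter, no default claimed), partial-volume
optics, sub-resolution texture, optical blur/PSF, stage/stitching
artifacts, or EM-scale content.  Passing round-trip tests therefore shows
the measurement path is consistent with the forward model — not that the
model matches any particular real acquisition.

## Contrast measurement

Images are normalized by an affine map of the 0.1/99.9 percentiles to
[0, 1] (plain min–max available); constant images are rejected.  ROI pairs
are 11×11 px squares (reproducible, unlike hand-drawn regions): the cell
square fully inside cytoplasm/nucleus, the surround square fully inside
neuropil within 40 px of it, cell centers ≥ 25 px apart, all seeded; 50
pairs is the reference count.  Per pair the contrast is the ratio of mean
brightnesses; the estimate averages per-pair values (not pooled pixels) and
reports mean, SD and n.  Ratio contrast is invariant under positive scaling
but not offsets — hence the normalization step; Michelson mode is invariant
under positive affine maps.  Pairs whose darker mean is exactly 0 are
excluded and counted.

## Reproducibility

All randomness flows from integer seeds through `numpy.random.default_rng`.
The CLI derives per-stage child seeds from the global seed as
`(seed·1000003 + stage_index) mod 2³¹` so stages can be re-run
independently.  Output files (TIFF/CSV/JSON/YAML) contain no timestamps;
identically seeded reruns are byte-identical.

## Known limitations

- Absolute contrast predictions inherit the uncertainty of the placeholder
  stain constants; only trends and mechanisms are meaningful without
  measured n/k for the actual stained sections.
- The p-polarization transmittance of an absorbing substrate uses the
  standard admittance formula; for strongly absorbing substrates at large
  angles the partition between T and A is convention-dependent (R is not).
- NA averaging is defined about normal incidence only, and uses scalar
  (non-vectorial) optics — adequate for NA ≤ 0.6, not for high-NA oil
  objectives.
- The period estimator needs ≥ 2 oscillations and a few percent of
  prominence; heavily damped traces bias it slightly short.
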