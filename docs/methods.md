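# Methods

This note documents the models, conventions and numerical choices behind
each readout, what the synthetic generators do and do not emulate, and the
known limitations.

## GLCM texture and the mean correlation distance

The grey-level co-occurrence matrix P(i, j | d, θ) is the joint probability
of grey levels i and j at pixel offset d and orientation θ, counted
symmetrically (both directions) with out-of-image pairs dropped.  Images are
linearly quantised to 64 grey levels before counting (a configurable knob;
64 bounds the table size while retaining contrast resolution — integer
images already in range are passed through so hand-built level images stay
exact).  The Haralick correlation of a table is
c = Σᵢⱼ (i−μ)(j−μ) P(i,j) / σ², with μ, σ² the marginal mean and variance;
it is undefined (an error, not a silent 0) for constant images.

The correlation profile evaluates c at offsets 1..100 in 1-pixel steps at
0°, 90°, 180° and 270°, averaging the *correlation values* over the four
orientations (not the tables).  Under symmetric counting 0° ≡ 180° and
90° ≡ 270°, so the four-orientation average equals the two-orientation one;
both are kept for interface fidelity.

The profile is summarised by the mean correlation distance
D = Σᵢ dᵢ·ĉ(dᵢ) / Σᵢ ĉ(dᵢ).  The weights ĉ are taken from the leading
positively-correlated stretch of the profile: offsets are kept up to the
first non-positive correlation and any residual negative values are clamped
to zero.  Truncation matters: beyond the first zero crossing the profile is
sampling noise around zero, and keeping its positive fluctuations (clamping
alone) lets arbitrary far offsets dominate the tiny denominator — measured
on synthetic fields this made D non-monotone in the imposed correlation
length and pushed D toward ~50 px for white noise.  With truncation, D is
~1 px for white noise and rises monotonically (medians 1.5 / 3.4 / 5.8 /
10.6 px for correlation lengths 2 / 5 / 10 / 20 px at 256²).

SHG coverage is the percentage of pixels above threshold per z-slice; the
peak slice is the comparison statistic.  The default threshold is Otsu's,
derived once from the pooled stack so slices are comparable; a fixed
threshold can be supplied instead.

## Structure-tensor fibre orientation

Gradients are the continuous spatial derivatives of the cubic B-spline
interpolant: the image is prefiltered to B-spline coefficients and the
interpolant's derivative is evaluated on the pixel grid, which reduces to
the kernel [+0.5, 0, −0.5] applied to the coefficients.  The tensor
components Jxx = ⟨Ix²⟩, Jxy = ⟨Ix·Iy⟩, Jyy = ⟨Iy²⟩ are Gaussian-averaged
with σ = 2 px by default (configurable).  The fibre axis — the direction of
least intensity variation, i.e. the minor eigenvector — is
θ = ½·atan2(2 Jxy, Jyy − Jxx), wrapped to [0, 180).

**Convention.** Orientations live on the half-circle [0, 180) measured
counter-clockwise from the image x-axis *as displayed* (rows grow
downward).  The synthetic fibre generator uses the same convention, so
recovery tests compare like with like; peak-shift tests under image
rotation compare unsigned circular distances and are convention-free.

The orientation histogram uses 180 one-degree bins (fine enough for the
narrowest ±5° band), weighted by tensor energy Jxx + Jyy by default so
featureless background does not vote (an unweighted switch exists).  Peak
alignment is the centre of the maximal bin, ties resolved to the smallest
angle for determinism.  Band frequencies sum the bins whose centres fall in
[peak − w, peak + w) circularly; the half-open interval makes a ±45° band
over a uniform histogram exactly 90/180 = 0.5.

Accuracy note: discrete gradient estimation attracts orientations toward
the diagonals by up to ~±(1–5)° when fibres are only 2–3 px wide; at the
generator's default 4 px width the residual bias is ≲1°, which is why the
synthetic micrographs render fibres resolved over several pixels.

## Picrosirius-red birefringence and IHC

Pixels are classified by inclusive boxes in 8-bit HSB space — red-orange
H 0–29 / B 70–255, yellow H 30–44 / B 70–255, green H 45–245 / B 70–200 —
and relative areas are percentages of the total-fibre mask H 0–245 /
B 70–200 (S unrestricted throughout).  The red/yellow brightness caps (255)
deliberately exceed the total-fibre cap (200); rather than silently
"correcting" the boxes, class pixels outside the denominator are counted
and reported, so a very bright scene can show relative areas above the
naive within-mask shares, flagged in the output.

Transmitted-light picrosirius coverage uses red-channel dominance
(R − max(G, B) ≥ 20 and R ≥ 60 by default); DAB coverage converts to
optical density OD = −log₁₀(I/255) per channel, unmixes through the
standard haematoxylin/DAB/residual stain matrix (configurable; must be
non-singular) and thresholds the DAB channel at OD 0.15.  The mix→unmix
round trip is exact by construction.  ROI scoring consumes already-scored
cell records (detection is manual in the motivating assay): counts per
500 × 500 µm grid cell by centroid membership, half-open intervals so
shared-edge cells count once, with an explicit µm-per-px calibration
required for pixel coordinates.

## Hertz force-curve analysis

Approach curves (z in µm increasing with indentation, force in nN) are
baseline-corrected by subtracting a line fitted to the first 30% of
samples.  The contact point minimises, over every candidate sample, the
total squared residual of the piecewise model F = 0 before contact and
F = k·δ^{3/2} after (k closed-form per candidate) — exhaustive and
deterministic.  A curve is declared contact-free when the fitted signal
amplitude at full indentation is below 5× the residual noise; a
residual-improvement criterion was rejected because baseline-extrapolation
tilt lets the δ^{3/2} term "explain" a sizeable share of pure-noise curves.

The modulus follows from F = (4/3)·E/(1−ν²)·√R·δ^{3/2} with ν = 0.5
(incompressible soft matter) and tip radius 0.5 µm by default — a "1 µm
spherical colloidal probe" is read as a diameter; both are configurable.
With z/δ in µm and F in nN the unit factors cancel exactly
(F_nN = (4/3)(E/(1−ν²))√(R_µm·10⁻⁶)·δ_µm^{3/2}).  Only approach curves are
modelled; adhesion, non-Hertzian geometries and substrate corrections are
out of scope.  Force-map summaries report mean/median/SD across successful
fits (failures counted, never imputed) and per-area means for the
3-area × 9-point grid layout.  Matrix thickness is the absolute difference
of the surface-contact and dish-contact z positions, reported in mm.

## Invasion scoring

Counts arrive per ROI: surface cells, invaded cells in half-open depth bins
[0,100), [100,200), [200,300), [300,∞) µm, and marker positives out of
total.  Invasive index = 100·invaded/(invaded + surface); marker index =
100·positive/total; depth profile = per-bin invaded/surface.  Aggregation
averages ROIs within a replicate first and reports mean ± SEM across
replicate means — the biological replicate is the unit of analysis.
Vehicle normalisation divides each condition's per-bin mean ratio by the
vehicle's; bins where the vehicle ratio is zero are flagged non-comparable
rather than producing infinities, and the operation is idempotent.

## Comparative-CT expression and statistics

Per sample, ΔCt = Ct_gene − Ct_housekeeping; ΔΔCt is the difference of
group mean ΔCt (treatment − reference); fold change = 2^(−ΔΔCt).  The SEM
of ΔΔCt combines the two group SEMs in quadrature by default (switchable to
treatment-only, since some workflows treat the calibrator as fixed); the
fold-change interval exponentiates ΔΔCt ∓ SEM — symmetric in log₂ space,
asymmetric linearly.  A two-fold flag (FC ≥ 2 or ≤ 0.5) gates reporting,
following MIQE practice.  Coverage caveat: with SEM estimated from n = 4
replicates per group the pivot (ΔΔCt − truth)/SEM is t-distributed with
~6 degrees of freedom, so a ±2·SEM interval covers the truth ~90% of the
time, not the Gaussian 95% — the calibration tests assert the t-correct
value.

Collagen abundance is 100 × [Sircol collagen]/[Lowry total protein];
values above 100% are physically impossible and flagged, not rejected.
The t-tests are thin wrappers over equal-variance two-sample (Welch
optional) and one-sample Student's tests with the conventional */**/***
tiers; degenerate zero-variance inputs return t = 0, p = 1 when means
agree instead of NaN.  No multiple-testing correction is applied by
default, matching common single-figure qPCR practice.

## Synthetic data: what it does and does not emulate

Generators are pure functions of their spec including the seed
(bit-reproducible) and always return ground truth alongside the data.

* **Fibre fields** draw axial orientations from a von Mises distribution on
  the doubled angle (κ = 0 → isotropic) and render Gaussian-profile
  anti-aliased strokes; accumulated intensity is normalised by its maximum
  rather than hard-clipped, because saturated crossing plateaus measurably
  bias orientation statistics (~+6° on concentrated fields).  Defaults:
  4 px fibre width, stroke length 60% of the image side, additive intensity
  noise SD 0.02.
* **Textures** smooth white noise with a periodic Gaussian filter of
  σ = ℓ/2, giving squared-exponential autocorrelation exp(−(d/ℓ)²), then
  rescale to [0, 1].
* **Force curves** evaluate the Hertz forward model on a z grid spanning
  0.75·δ_max of pre-contact travel plus δ_max of indentation (400 samples
  default) with optional additive Gaussian force noise.
* **Histology scenes** assign pixel classes by the stated fractions and
  sample H/S/B uniformly inside each class's box intersected with the
  total-fibre box (background samples below the brightness floor), so the
  stated fractions are fractions of the fibre total.
* **Count sheets** use Poisson surface/bin counts and binomial marker
  positives — the simplest count-noise model for per-ROI scoring.
* **Ct tables** shift the treatment group's ΔCt by −log₂(fold change) with
  Gaussian Ct noise.

None of this emulates optics (no PSF, no depth attenuation), 3D fibre
networks, stain chemistry variability, cell morphology or scanner effects.
Passing tests therefore demonstrate that the *estimators* are correct and
well-calibrated on data matching their model assumptions — not that the
pipeline is robust to every artefact of real microscopy.

## Problem sizes

Test and driver workloads use 256²–512² images, 5 seeds per condition for
median-based comparisons, 20 seeds × 3 moduli for noisy Hertz recovery,
200 simulations for interval coverage and 2000 replicates for type-I-error
calibration — sizes at which the Monte-Carlo error is comfortably below
each assertion's tolerance.
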