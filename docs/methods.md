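# Methods

`cellmech` models the nanomechanical characterization of adherent cancer
cells by colloidal-probe atomic force microscopy (AFM) and the analyses
built on top of it: stiffness-subpopulation deconvolution, dose-response
and stiffness-response metrics, morphology classification, fluorescence
profiling, and the association statistics over a cell-line summary
table. This note records the models, the defaults and their rationale,
and the known limits of the synthetic data used for validation.

## Units

Fixed internal convention: Young's modulus in kPa, force in nN,
deflection and indentation in nm, piezo position in µm, spring constant
in N/m (1 N/m × 1 nm = 1 nN). Converters are the caller's concern.

## Indentation model and its inverse

A rigid sphere of radius R pressed a depth δ into an elastic half-space
experiences the Hertzian force

    F = (4/3) · E/(1 − ν²) · √R · δ^{3/2},

with E the apparent Young's modulus and ν the Poisson ratio. Cells are
treated as incompressible (ν = 0.5, the standard assumption for water-
dominated cytoplasm). The probe is a 4.5 µm silica bead (R = 2.25 µm) on
a soft triangular cantilever; of the lever's two nominal spring
constants (0.32 and 0.08 N/m) the softer one is the default, because at
kPa-scale moduli it converts the available force budget into the larger,
better-resolved deflection signal. The approach stops at a 2 nN
deflection trigger to protect the cell.

The measured quantities are piezo extension z and cantilever deflection
d; force is F = k·d and indentation follows the standard AFM convention
δ = (z − z_c) − d, with z_c the contact point. Inversion proceeds in
separable stages:

1. **Baseline correction** — a straight line fitted to the first 30% of
   points (assumed contact-free) is subtracted, removing optical offset
   and tilt.
2. **Contact detection** — a two-segment model (flat zero baseline
   before z_c, Hertz force law after, with E profiled out in closed
   form) is scanned over candidate contact positions; the total residual
   sum of squares is minimized, first on a coarse grid, then at single-
   point resolution, then continuously between the flanking grid nodes.
   A candidate is accepted only if it reduces the flat-model RSS by at
   least 2% (relative) with a positive modulus. The threshold was
   calibrated against the null: on pure-noise curves the best achievable
   improvement stays below ~1%, so 2% rejects no-contact data while
   keeping genuinely soft cells.
3. **Hertz fit** — with z_c fixed, E is the single free parameter of
   F = A·E·δ^{3/2} on the window 0 < δ ≤ 500 nm (the depth that indents
   cells of different heights while remaining in the linear-elastic
   regime); the least-squares solution is closed-form. Curves that never
   reach 100 nm indentation are rejected as quality failures. A joint
   (E, z_c) refinement exists but is off by default — the separable
   stages are individually testable.
4. **Per-cell aggregation** — the arithmetic mean of ≥ 5 converged
   per-curve moduli (median available). Cells with fewer than five
   converged curves are excluded with a logged reason, mirroring the
   ≥ 5-indentations-per-cell protocol.

Retract segments, viscoelastic relaxation, hydrodynamic drag and
bottom-effect corrections are out of scope; the indentation velocity
(2 µm/s) is metadata only.

## Synthetic force curves

The generator runs the same physics forward. Deflection past contact
solves the implicit balance k·d = A·E·(s − d)^{3/2} (s = piezo travel in
nm) by a vectorized damped Newton iteration; the curve is truncated at
the trigger force; baseline offset, tilt and additive Gaussian
deflection noise are applied on top. Ground truth (E, z_c) rides along
with every curve.

Defaults and why:

- **z grid**: 3.5–6.0 µm with contact at 5.0 µm, 1000 points (~2.5 nm
  spacing). This matches kHz-rate acquisition at 2 µm/s; at this density
  the contact detector reaches ~47 nm median error on 0.5 kPa cells even
  under 2 nm deflection noise.
- **Deflection noise: 0.25 nm SD.** The soft lever's thermal motion sets
  the physical floor, √(k_BT/k) ≈ 0.23 nm at 310 K for k = 0.08 N/m.
  Real instruments add detector noise, so the parameter is exposed; at
  e.g. 2 nm the noise floor rises to E ≈ 0.05 kPa and the softest tail
  of a population becomes unmeasurable (see Limitations).
- **Within-cell curve-to-curve modulus CV: 10%**, standing in for local
  membrane/cytoskeleton heterogeneity across the peri-nuclear
  indentation sites; configurable.
- **Per-cell moduli**: positive-truncated Gaussian (mixture) draws —
  the distribution family the downstream deconvolution assumes; the
  truncation guard rejects after 100 attempts.

## Stiffness-distribution deconvolution

Per-cell moduli of one line are fitted with one- and two-component
Gaussian models (EM, k-means initialization, 10 restarts, fixed seed).
The two-component model is selected — the line labeled **Bimodal** —
only when all of: BIC₂ < BIC₁ − 2; both weights ≥ 0.1; mean separation
exceeds one pooled SD (√ of the weight-averaged component variance).
The guards suppress spurious bimodality from heavy tails or a few
outlying cells; the decision is invariant to unit changes (kPa vs Pa)
and sample order. Measured operating characteristics at n = 100 over
100 runs: ~1% of single-Gaussian samples mislabeled Bimodal; 100%
detection of 50/50 mixtures with 3:1 mean separation. A histogram mode
(least-squares Gaussian peaks on a Freedman–Diaconis histogram,
initialized at the tallest separated modes) mirrors figure-style peak
deconvolution but is not the default; fitting is on the linear kPa
scale, with an optional log transform off by default. Models with ≥ 3
components and formal dip-type modality tests are out of scope.
Distribution fitting requires ≥ 20 cells.

## Dose-response and stiffness-response metrics

Viability (percent of untreated) against drug concentration follows the
four-parameter logistic v(c) = bottom + (top − bottom)/(1 + (c/IC50)^h),
fitted by least squares on log₁₀ concentration with top fixed at 100
(MTT data are normalized to the untreated control) and bottom free in
[0, 50]; a fully free variant exists. Data that are flat (< 10
percentage points of range) or increasing with dose raise a no-IC50
error. Noiseless curves generated from any published IC50 on the
1–2–4–10–20–40–80 µM grid refit to 4 significant digits; with 5-point
viability noise the median bias is < 10%.

The treatment-response metric CV% is implemented in two modes because
the name (a coefficient of variation) and the usage (the extent of
stiffness change after treatment) point to different quantities:

- **relative-change** (default): 100·(mean_E_control − mean_E_treated)/
  mean_E_control, floored at 0 so the invariant CV% ≥ 0 holds; the raw
  control and treated means are always stored, so a stiffening response
  remains visible.
- **treated-dispersion**: 100·SD/mean of the treated per-cell moduli.

Both values are computed on per-cell (not per-curve) moduli and stored
regardless of mode. For bimodal lines, the same relative-change metric
applied to rank-matched component means (softer↔softer,
stiffer↔stiffer) gives the per-component CV%.

## Morphology and fluorescence profiles

From a single-cell binary mask (one connected component, ≥ 100 px):
circularity = 4π·area/perimeter² with the Crofton perimeter estimator
(less rasterization bias than edge counting; values pushed above 1 by
digitization are capped at 1.05), and aspect ratio = major/minor axis of
the second-moment ellipse. A cell is **fibroblastic-like** only when
circularity < 0.5 AND aspect ratio > 2.5; otherwise epithelial-like.
On rasterized test shapes a disk gives circularity ≈ 1.0 (epithelial)
and a 5:1 ellipse ≈ 0.45 with AR 5 (fibroblastic), matching the
Ramanujan-perimeter hand calculation; shapes exceeding only one
threshold stay epithelial.

The fluorescence profile runs along the major-axis crossline through the
mask centroid: in-mask pixels within a 3 px half-width band of the axis
(a single-pixel line is too noise-sensitive) are split into 10
equal-length segments; each bin is the band's mean pixel intensity
(m.p.i.) there. Bins 4–7 read the cell center, bins 1–3 and 8–10 the
periphery. The count-weighted mean of the bins equals the band's overall
m.p.i. exactly, and mirroring the image reverses the profile (exactly
when no pixel sits on a bin edge; bins are right-open). Per-cell
profiles average across cells with 95% t-intervals. The uptake ratio is
cell m.p.i. over background m.p.i., the background defaulting to a 10 px
border frame minus any cell pixels. Segmentation from raw fluorescence,
colocalization and nuclear analysis are out of scope — masks are inputs.

## Association layer

Over the packaged eight-line summary table (one row per line:
morphology class, mean ± SD stiffness, distribution pattern,
invasiveness score, IC50, CV%): ordinary least squares with R² and the
two-sided slope p; group comparisons choosing parametric (Welch t /
ANOVA) vs rank tests (rank-sum / Kruskal–Wallis) by Shapiro–Wilk on
within-group residuals at α = 0.05; median dichotomization into
high/low (cutoff = sample median, ties to "low"); Pearson chi-squared
without continuity correction. Reported group means and cutoffs are
rounded to the nearest integer. All published statistics are recomputed
from the fixture CSV at run time, never hard-coded.

Expression tables are normalized per sample by the geometric mean of the
three housekeeping genes HPRT1, HMBS and PPIB; differential expression
is a per-gene Welch t-test on log2-normalized values with log2FC the
difference of group log2 means, flagged at uncorrected α = 0.05 (the
correction is optional and off). One caveat measured here: with only
three housekeeping genes, the normalization injects a shared per-sample
offset that correlates genes, so the per-dataset fraction of null genes
flagged is volatile (3–25% in individual runs) even though the t-test
itself is calibrated — on unnormalized null data the false-positive
fraction averages 0.050. Type-I checks therefore target the test
operation directly.

## What the synthetic data do and do not show

The generators reproduce: Hertzian contact with trigger truncation,
baseline artifacts and additive Gaussian noise; Gaussian (mixture)
stiffness populations; 4PL viability; elliptical cells with radial
intensity patterns; log-normal expression with planted fold changes.
They do not reproduce: viscoelastic or height-dependent indentation
artifacts, non-Gaussian stiffness tails, cell segmentation errors,
irregular cell outlines (shape tests use ellipses and lobed analytic
shapes), or count-based RNA-seq noise. Passing recovery tests therefore
demonstrates the correctness of the inverse methods under their own
model assumptions, not robustness to every artifact of real AFM or
imaging data.

Problem sizes in the packaged analyses: recovery runs use 100 cells × 5
curves (the drivers use 50 cells), classifier operating characteristics
use 100 runs at n = 100 cells, null expression checks 1000 genes × 2×10
samples. With truncated-Gaussian population sampling at n = 100 the
grand-mean SE is ~4% of the mean for the benchmarked lines, so
single-run recovery error is dominated by the population draw, not the
estimator (which tracks the realized sample mean to ~1–2%).

## Degenerate inputs and tie-breaks

All-zero or pure-noise deflection → no-contact error; fewer than 10
points or < 100 nm depth in the fit window → fit error; < 5 converged
curves → cell excluded; < 20 cells → no distribution fit; flat or
rising viability → no-IC50 error; masks with zero or multiple
components, line-like masks, crosslines < 10 px, empty profile bins,
zero background m.p.i. → explicit errors. Mixture components are always
reported sorted ascending (softer = index 0); dichotomization ties go
to "low"; histogram-mode weights are Gaussian peak areas normalized to
1.
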