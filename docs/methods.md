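# Methods

`cedbt` implements an image-reconstruction chain for contrast-enhanced
digital breast tomosynthesis (CE-DBT): dual-energy scans of a breast-like
object containing iodinated contrast agent (ICA) are reconstructed,
normalized, and subtracted to isolate the iodine distribution.  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic studies do and do not demonstrate.

## Forward model and geometry

A DBT acquisition is modelled as cone-beam projection over a partial arc:
the source travels on a circle of radius `source_to_detector_distance −
rotation_axis_height` in the y–z plane above a stationary flat detector
at z = 0 (25 views over a 50° arc by default).  Preprocessed data are
line integrals: transmission counts divided by a flood field and passed
through the negative logarithm, so `g = Xf` with `f` the attenuation
volume (1/mm) on a cubic-voxel grid and `X` the projection matrix.

The projector is ray-driven (Joseph-style): each source-to-pixel ray is
sampled at the voxel planes of its dominant axis with bilinear
interpolation and weighted by the per-slab intersection length.  The
back-projector is the literal matrix transpose of the forward projector
(verified by dot-product tests to rounding error); the primal-dual solver
requires a true adjoint pair.  Rays are treated as full lines through
source and pixel, so wide test arcs beyond ±90° remain well defined even
though no physical flat-panel system could acquire them; rays that miss
the volume contribute exactly zero.

The scanner class this emulates has a native detector pitch of 85 µm;
reconstruction operates at 8× reduced resolution, i.e. 680 µm working
pixels (`make_dbt_geometry(detector_pitch=None, binning=8)`).  The
source–detector distance (650 mm) and rotation-axis height (47 mm) are
plausible values for this scanner class, not measured ones, and are fully
configurable.  The desk-scale study geometry uses 1 mm detector pixels
and a 128×128×64 grid of 1 mm voxels so the whole chain runs in minutes
on one core; a full-scale configuration (188×417×175 at 680 µm) is a
configuration choice away.

## Ramp filtering

The data-fidelity term compares ramp-filtered measured and estimated
data.  Filtering is 1D along the detector axis parallel to the source
travel (the tomographically sampled direction), implemented by
zero-padded (2×) frequency-domain multiplication with the transform of
the discrete Ram-Lak sequence

    h[0] = 1/(4τ²),   h[n odd] = −1/(π² n² τ²),   h[n even] = 0,

which avoids the DC bias of sampling |ν| directly.  The circularly
embedded kernel is even, so the operator is exactly self-adjoint.  An
optional Hann window is available for FBP use; none is applied by
default.

Frequencies are measured in cycles per cm (`filter_pitch_cm`), the usual
lp/cm convention of tomography.  This choice fixes the otherwise
arbitrary overall scale of R and thereby gives the data-error tolerance
ε (an RMSE over filtered samples) its intended meaning: for a 4 cm
breast-scale object the default ε = 0.01 is about 1% of the filtered
data RMS.  On a per-mm frequency scale the same numeric tolerance would
exceed the entire filtered-data energy and the constraint would be
satisfied by the zero volume.

## Directional-TV reconstruction

The reconstruction solves

    min_f  α‖∇x f‖₁ + α‖∇y f‖₁ + (2−α)‖∇z f‖₁ + β‖f‖₁
    s.t.   ‖R(g − Xf)‖₂ ≤ ε√N   and   f ≥ 0

with forward differences (Neumann boundary) for ∇.  α ∈ (0, 2) shifts
penalty from the depth direction (z) to the in-plane directions: α = 1
is plain anisotropic TV; α = 1.75 (default) tolerates depth gradients,
which counteracts the depth elongation caused by the missing angular
range.  β (default 0.1) encourages pixel sparsity and confines the
reconstruction to the object support.  ε (default 0.01 RMSE over
filtered samples) is converted to an absolute ℓ2 radius internally.

The problem is convex and solved with the Chambolle–Pock primal-dual
algorithm on the stacked operator K = [∇x; ∇y; ∇z; R∘X]:

- weighted-ℓ1 dual blocks are clipped componentwise to [−w, w];
- the ε-ball dual block is ℓ2 shrinkage of `y + σ(RXf̄ − Rg)` by σε;
- the primal prox is one-sided soft thresholding `max(0, f − τβ)`,
  so non-negativity holds exactly at every iterate.

Steps satisfy στ‖K‖² < 1 with ‖K‖ from a seeded power method (50
iterations, well within 1% of a dense-SVD reference) and a 0.99 safety
factor; θ = 1; initialization f = 0, duals = 0, making runs
deterministic.  Because the ε-ball is invariant under scaling R and ε
together, the solver internally normalizes the filtered block to unit
peak gain; this balances K's blocks (gradients have norm ≤ 2) and is
essential for usable convergence — without it the iteration stalls for
thousands of iterations.  The `step_ratio` parameter trades primal
against dual step size; small values (0.02–0.1) converge fastest on the
instances studied here.

Stopping is a fixed iteration count (no early stopping), with the
objective recorded every iteration and the filtered-data residual
sampled periodically.  Small 2D instances run to convergence agree with
an independent ADMM solution of the identical discretized problem to
better than 1e-3 relative ℓ2 (typically 1e-5).  The desk-scale 3D study
uses a 300-iteration budget per energy: the residual is still shrinking
when the budget ends, but the image-domain comparisons (depth FWHM,
iodine contrast) are stable well before full constraint feasibility,
which at this scale requires several thousand iterations.

## FBP reference

The comparison baseline is deliberately plain: `(π/n_views)·Xᵀ(Rg)` with
the shared projector and ramp filter, no depth-dependent weighting.  It
reproduces the classic limited-angle behaviour — objects elongated along
z with FWHM several times their true diameter.

## Background normalization

Limited-angle reconstructions carry smooth low-frequency shading that
differs between beam energies, so raw volumes cannot be subtracted
directly.  Per in-plane slice `s`:

1. the object support `m` is estimated by thresholding at 0.2× the
   median positive intensity, keeping the largest connected component
   and filling holes (Otsu and fraction-of-mean thresholds available);
2. a background `b = Pc` is fitted by minimizing `‖m·(s − Pc)‖₁`, where
   P holds all 2D monomials xⁱyʲ with i+j ≤ 8 (45 terms) on coordinates
   normalized to [−1,1]² and with unit-norm column scaling for
   conditioning.  The ℓ1 objective is solved by iteratively reweighted
   least squares with weights `1/max(|r|, δ)`, δ = 1e-6×median |s| on
   the mask, up to 50 reweightings or relative coefficient change below
   1e-8.  The robust fit ignores compact high-contrast structures, so
   inserts are not absorbed into the background (verified against an
   exact linear-programming ℓ1 fit);
3. the displayed slice is `fd = m·s/b` with `b` floored at 5% of its
   on-mask median, so artifact-free tissue centres on 1.

## Dual-energy subtraction

With low-energy (30 kV/Al) and high-energy (49 kV/Ti) normalized volumes,

    f_ICA = (fd_HE − 1) − w·(fd_LE − 1).

Iodine's K-edge at 33.2 keV makes its effective attenuation roughly
double between the two beams while tissue contrast halves, so a weight w
exists that cancels the glandular texture yet leaves inserts positive.
The module refuses un-normalized inputs unless overridden, since raw
volumes carry energy-dependent shading that subtraction cannot remove.
Instead of choosing w by eye, `select_weight` sweeps candidates and
minimizes the variance of the difference over a background region (ties
break toward smaller w); on the synthetic phantom the selected w agrees
with the attenuation-table ratio to a few percent.

## Synthetic phantom and noise

The generator emulates a structured breast phantom: a 40 mm slab with an
elliptical in-plane outline, heterogeneous adipose/glandular texture at
50% glandularity (Gaussian-filtered seeded noise thresholded at the
empirical quantile, 5 mm correlation length), and spherical ICA inserts
of 2/3/5/8 mm diameter at 1/2/3/5 mg/mL arranged diameter × concentration
at mid-depth (cylinders optional).  Each beam is monoenergetic with
effective attenuation per material (editable `SpectralModel`, defaults
in 1/mm: adipose 0.050/0.030, glandular 0.062/0.036, iodine per mg/mL
0.0025/0.0050 at LE/HE) chosen so tissue contrast is small and the
iodine HE response is twice LE, reproducing the K-edge asymmetry.

Scan simulation follows the physical preprocessing: line integrals →
Poisson counts at a stated incident fluence → flood division → negative
log (zero counts are clamped to one with a warning).  The default
fluence, 2×10⁸ photons/pixel, is chosen so the ramp-filtered noise floor
sits below the solver's ε — the same relationship a practitioner creates
when tuning ε just above the noise on real data; with the earlier draft
value of 10⁶ the constraint radius lies far below the filtered noise and
the solver is asked to overfit noise it can never remove.  A delta-method
check confirms the post-log noise std `exp(ℓ/2)/√fluence` within 10%.

What the phantom does not model: polyenergetic spectra and beam
hardening, scatter, detector blur/MTF, the swirled texture geometry of
commercial structured phantoms, compression, or anatomical variability.  Passing tests
therefore demonstrate algorithmic correctness and the limited-angle
resolution behaviour, not clinical performance.

## Study problem sizes

Desk-scale end-to-end study: 128×128×64 volume at 1 mm, 25 views/50°,
176×128 detector at 1 mm, 300 CP iterations per energy (~10 min total on
one core).  Solver-correctness study: 32×32 2D instance, 9 views, CP vs
dense ADMM.  Dense-arc sanity: 60 views over 300°, noiseless, relative
ℓ2 recovery error < 2%.  These sizes are the package's test
configuration; all are plain configuration values.

## Known limitations

- The CP iteration converges slowly in constraint residual at 3D scale;
  fixed iteration budgets are reported with their diagnostics rather
  than silently treated as converged.
- FWHM is measured on axis-aligned single-voxel profiles with linear
  interpolation; for small inserts (≤ 2 voxels) it is quantization
  limited.
- The subtraction weight is global; spatially varying spectral response
  (beam hardening) would need a local weight or projection-domain
  decomposition, which is out of scope.
- Gray values in f_ICA are not calibrated to mg/mL; the chain is
  image-domain and qualitative by design.
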