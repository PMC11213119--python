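# cedbt — contrast-enhanced digital breast tomosynthesis reconstruction

Digital breast tomosynthesis (DBT) scans a compressed breast over a
narrow arc (here 25 views spanning 50°), so reconstructed volumes suffer
*depth blur*: every object is smeared along the detector normal, roughly
in proportion to its size.  For contrast-enhanced DBT (CE-DBT) — where
dual-energy scans bracketing iodine's 33.2 keV K-edge are subtracted to
image an iodinated contrast agent (ICA) — that blur prevents outlining
lesions or estimating their volume.

`cedbt` implements a reconstruction chain that restores nearly isotropic
resolution for the ICA distribution:

1. **Directional-TV reconstruction.**  Solve the convex problem

       min_f  α‖∇x f‖₁ + α‖∇y f‖₁ + (2−α)‖∇z f‖₁ + β‖f‖₁
       s.t.   ‖R(g − Xf)‖₂ ≤ ε   and   f ≥ 0

   with X the cone-beam projector, R a 1D ramp filter along the source
   travel direction (de-emphasizing low-frequency sinogram mismatch and
   preconditioning the data term), α = 1.75 shifting gradient penalty
   from depth to in-plane directions, β = 0.1 an ℓ1 support penalty, and
   ε the data-error tolerance (0.01 RMSE over filtered samples).  The
   solver is the Chambolle–Pock primal-dual algorithm with a matched
   projector/back-projector pair (exact adjoints).  A plain FBP
   (`(π/n_views)·XᵀRg`) serves as reference.
2. **Background normalization.**  Limited-angle shading is removed per
   slice by a robust ℓ1 polynomial fit (degree 8, 45 terms, solved by
   IRLS) on the thresholded object support; the slice is divided by the
   fitted background, so tissue centres on 1.
3. **Dual-energy subtraction.**  `f_ICA = (fd_HE − 1) − w(fd_LE − 1)`,
   with w chosen automatically by minimizing background variance over a
   sweep.

A synthetic dual-energy phantom generator (4 cm slab, 50% glandularity
texture, ICA spheres of 2/3/5/8 mm at 1/2/3/5 mg/mL, Poisson counting
noise, flood-field/log preprocessing) makes the whole chain runnable and
testable without scanner data.  See `docs/methods.md` for models,
parameter meanings and limitations.

## Worked example

```python
import cedbt

cfg = cedbt.PipelineConfig(seed=7, output_dir="run_desk")
res = cedbt.run_pipeline(cfg)          # ~8 min on one core

truth = res["truth"]
center = [i["center_mm"] for i in truth.inserts
          if i["diameter_mm"] == 8.0 and i["concentration_mgml"] == 5.0][0]
for method in ("dtv", "fbp"):
    fw = {ax: cedbt.profile_fwhm(res[f"ica_{method}"], cfg.grid, center, ax)
          for ax in "xyz"}
    print(method, res[f"weight_{method}"], fw)
```

Output from this exact run (desk-scale 128×128×64 phantom, 25 views/50°):

```
dtv 0.9 {'x': 7.87, 'y': 8.03, 'z': 7.28}
fbp 0.8 {'x': 7.32, 'y': 6.22, 'z': 20.12}
```

Read it as: in the iodine image of the 8 mm, 5 mg/mL insert, FBP smears
the insert to a 20.1 mm full width at half maximum in depth (2.5× its
true size), while directional TV yields 7.3 mm — within a voxel of the
true diameter and essentially isotropic (z/x ≈ 0.93).  The normalized
backgrounds centre on 1.008, and mean iodine-image intensity in the 8 mm
inserts rises monotonically with concentration
(0.02 → 0.20 → 0.44 → 0.58 for 1/2/3/5 mg/mL).

The same chain is scriptable from the shell:

```bash
cedbt run-all --out run_desk --seed 7
cedbt simulate --out sim --seed 1          # projections + truth only
cedbt reconstruct sim/projections_he.h5 --method dtv --out he.tif
```

`configs/full_scale.yaml` holds the clinical-resolution configuration
(188×417×175 grid of 680 µm voxels = the native 85 µm detector pitch
reduced 8×); it is hours of compute, so the desk scale is the default.

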