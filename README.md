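# hdrneedle

Automatic digitization of interstitial needles for CT-based high-dose-rate
(HDR) brachytherapy, built around an attention-gated 3D U-Net.

In interstitial HDR brachytherapy of cervical cancer, 3–6 hollow trocar
needles are inserted freehand and a radioactive source is stepped through
them. Before planning, every needle must be *digitized*: its 3D trajectory
identified in the planning CT so the planning system knows where the source
can dwell. Manual digitization is slow (up to ~15 min per plan), user
dependent, and sensitive to metal artifacts and touching needles. This
package implements the full automatic alternative and the evaluation
machinery to judge it:

1. **Segmentation** — a 3D encoder–decoder U-Net with additive attention
   gates on the skip connections and group normalization, trained with the
   soft Dice loss
   `L = 1 − 2|P∩T| / (|P| + |T| + ε)` (ε = 10⁻⁴).
   The gate computes per-voxel coefficients
   `α = σ₂(ψᵀ σ₁(W_x x + W_g g + b_xg) + b_ψ) ∈ [0, 1]`
   from the fine skip feature `x` and the coarser decoder gating signal
   `g`, suppressing background before the skip concatenation.
   The network is implemented directly on numpy arrays with hand-written
   backward passes (numba kernels for the 3×3×3 convolutions) and trained
   with Adam (lr 5×10⁻⁴, batch size 1).
2. **Digitization** — connected components of the predicted mask become
   needle instances; per-slice centroids form each central trajectory;
   least-squares polynomials x(z), y(z) smooth voxel quantization; dwell
   positions are placed along the fitted curve by arc length.
3. **Geometric evaluation** — Dice similarity coefficient, Jaccard index,
   exact Hausdorff distance (mm), per-needle tip error (mean |length
   difference|) and shaft error (mean in-plane centerline distance at
   common slices), plus a paired t-test between methods.
4. **Dosimetric evaluation** — a TG-43 1-D point-source dose engine
   `Ḋ(r) = S_K Λ (r₀/r)² g(r) φ_an(r)` with tabulated radial dose and
   anisotropy functions, exact-voxel-sort DVH metrics (HR-CTV D90/D100,
   OAR D2cc), and the manual-vs-automatic dose difference
   `ΔD = D_manual − D_automatic` (absolute and relative).

Since no patient data ship with the package, a seeded **synthetic phantom
generator** stands in for the study CTs: 1.5 mm-diameter bright tubes along
analytic polynomial centerlines in a soft-tissue body (0.8 mm in-plane,
5 mm slices), optional streak artifacts, an HR-CTV ellipsoid and two
organ-at-risk structures. The analytic ground truth makes every stage
testable end to end.

## Worked example

```python
import hdrneedle as hn

# a phantom with 4 curved needles on a 64x64x16 grid (0.8/0.8/5.0 mm)
vol, truth = hn.make_phantom(hn.PhantomConfig(n_needles=4, seed=7))

# digitize the ground-truth mask itself (noise-free recovery check)
trajs = hn.digitize_mask(truth.binary_mask)
pairs_idx, _, _ = hn.match_needles(trajs, truth.centerlines)
pairs = [(trajs[i], truth.centerlines[j]) for i, j in pairs_idx]
tip_err, _ = hn.tip_error(pairs)
print(f"tip error  {tip_err:.3f} mm")
print(f"shaft error {hn.shaft_error(pairs):.3f} mm")

# TG-43 dose and DVH for the target
src = hn.SourceModel.generic_ir192()
plan = hn.Plan([hn.sample_dwells(t, 2.5, 0.0, 5, 10.0, i)
                for i, t in enumerate(trajs)], src)
dvh = hn.compute_dvh(hn.dose_grid(vol, plan), truth.structures["hrctv"])
print(f"HR-CTV {dvh.structure_volume_cc:.1f} cc, "
      f"D90 {dvh.d90:.2f} Gy, D100 {dvh.d100:.2f} Gy")
```

Output:

```
tip error  0.701 mm
shaft error 0.070 mm
HR-CTV 118.8 cc, D90 0.82 Gy, D100 0.62 Gy
```

The tip error sits below half the 5 mm slice thickness (the tip of a
needle is quantized by the slice grid; the digitizer extrapolates half a
slice), and the shaft error is well under one in-plane voxel. The D90/D100
values are for uniform 10 s dwell times; the pipeline normalizes dwell
times to the prescription when comparing plans.

A shell interface wraps the same stages
(`hdrneedle generate|train|predict|digitize|evaluate|dose|compare|pipeline`);
`hdrneedle pipeline --seed 1 --out run/` executes the whole study on
synthetic phantoms and writes geometry/DVH reports plus a run manifest.

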