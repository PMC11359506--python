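# deitbone

Locating the central femur axis inside a thigh with **time-differential
electrical impedance tomography (DEIT)** — a computational phantom study.

Robotic knee-replacement systems today track the femur with pins screwed
into the bone. A non-invasive alternative is to drive small currents
(10 mA at 100 kHz) through a belt of 16 surface electrodes, measure the
resulting boundary voltages, and reconstruct where the electrically
near-insulating bone (cortical bone 0.02 S/m, marrow 0.002 S/m, versus
muscle 0.37 S/m) must sit. `deitbone` simulates that entire measurement and
estimation chain on tetrahedral FEM thigh phantoms and quantifies how
accurately the bone's position and axis direction are recovered.

## Method

1. **Phantom** — a layered thigh model (skin, subcutaneous fat, muscle,
   optional intramuscular fat pockets, cortical bone, marrow) as a
   conforming tet mesh; either a plain cylinder or a "realistic"
   cross-section produced by a smooth planar deformation. A single belt of
   sixteen 7 mm electrodes sits at mid-height `z_m`.
2. **Forward problem** — complete-electrode-model FEM solves
   `Y(σ) u = I` for opposite-pair current patterns; voltages are measured
   differentially between adjacent non-driving electrodes. The reference
   state `V1` uses all tissues; the *boneless* state `V0` replaces bone and
   marrow by muscle (three configurations of what else the boneless model
   knows: homogeneous; + skin/fat; + intramuscular fat).
3. **Difference imaging** — the conductivity change `Δσ` is reconstructed
   from `ΔV = V1 − V0` by minimizing

   `ε = ‖ΔV − J Δσ‖²_W + λ² ‖Δσ‖²_Q ,  Q = LᵀL`

   with the graph Laplacian `L` of the inverse mesh's element adjacency,
   `λ = 7·10⁻⁵`, solved by truncated conjugate gradients on the normal
   equations. The sensitivity matrix `J` comes from the adjoint-field
   method on an independently generated coarser mesh.
4. **Segmentation** — elements are sorted by `Δσ` and assigned to 15 bins
   around a detected flat background band; face-connected clusters are
   grown over the low bins (`b ≤ 7`), and small surface-touching clusters
   are discarded.
5. **Axis fit** — per cluster: outlier trim (mean ± 1.9 SD), SVD line
   initialization `n_b = v₁`, then a weighted cylinder fit

   `ε_r = Σ w_i² ‖p_i − p_b − ζ_i n_b‖² / r₀² ,  ζ_i = ⟨p_i − p_b | n_b⟩`

   with `r₀ = 1.5 cm`, minimized with L-BFGS-B. The cluster with the
   largest axial extent `Δζ` is taken to be the femur.
6. **Evaluation** — in-plane positional deviation `Δp_b` (mm, at the
   electrode plane) and angular deviation `φ = arccos |⟨n_b, n_f⟩|`
   (degrees) against the known marrow-centre axis.

## Worked example

```python
from deitbone import PipelineConfig, run_study, study_report

results = run_study(PipelineConfig(seed=1))
print(study_report(results).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
```

```
    model              config  initial_dp_mm  optimal_dp_mm  initial_phi_deg  optimal_phi_deg
 cylinder    cfg1_homogeneous           0.31           0.40             1.68             0.76
 cylinder       cfg2_skin_fat           0.44           0.48             0.74             1.35
realistic    cfg1_homogeneous          29.04          23.26             3.55             2.16
realistic       cfg2_skin_fat           7.35           5.75             3.74             3.81
realistic cfg3_skin_fat_intra           7.67           6.10             4.25             3.95
     mean                               8.96           7.20             2.79             2.41
```

Each row is one phantom/configuration combination: the cylinder rows are
the verification models (sub-millimetre positional recovery), the realistic
rows show how a deformed cross-section, fat shells and fat pockets degrade
the estimate. `initial` is the SVD stage, `optimal` the cylinder-fit
refinement; positions are electrode-plane distances in millimetres, angles
in degrees against the true marrow axis.

The same study is available from the shell:

```bash
deitbone run-all --seed 1 --out-dir out/
deitbone phantom --shape realistic --out-dir out/   # stage-by-stage variant
```

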