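# Methods

This note documents the models, parameter choices and numerical decisions
behind `deitbone`, and what the simulated study does and does not show.

## Phantoms

The thigh is modelled as an extruded disk: a ring-structured planar
triangulation (Delaunay over concentric node rings whose radii honour the
tissue interfaces) extruded into prism layers, each prism split into three
tetrahedra by the minimum-vertex diagonal rule, which is face-local and
therefore yields a conforming mesh. Axial layers are refined to half the
in-plane element size near the electrode belt, and the outer boundary is
refined azimuthally so each 7 mm electrode is covered by several boundary
faces.

Default dimensions (overridable; no authoritative values exist for the
simulated subject):

| quantity | value |
|---|---|
| outer radius | 70 mm |
| skin / subcutaneous fat thickness | 2 mm / 8 mm |
| cortical bone / marrow radius | 15 mm / 7 mm |
| length, electrode plane | 300 mm, `z_m` = 150 mm |
| in-plane element size | 8 mm (simulation), 11 mm (inverse) |

Conductivities at 100 kHz (S/m): skin 0.065, fat 0.03 (both compartments),
muscle 0.37, cortical bone 0.02, marrow 0.002. Only this frequency is
supported; the drive current of 10 mA rms is checked against the
piecewise safe-current limit (100 µA below 1 kHz, proportional up to
100 kHz, 10 mA beyond).

**Cylinder phantom**: concentric compartments, bone on the axis. It is the
verification model: by symmetry the reconstruction errors are nearly
unbiased and recovery is sub-millimetre.

**Realistic phantom**: every node of the cylinder mesh is pushed through a
smooth planar map — anisotropic scaling (1.25×/0.85×) plus first, second
and third angular harmonics whose amplitude grows quadratically from the
centre (0.04/0.08/0.05). The first harmonic makes the section
front-to-back asymmetric, as a real thigh is; without it the two
stretched ends of the fat shell produce mirror-image smear columns in the
difference image that the cluster-selection heuristic cannot tell apart.
The bone is offset 12 mm laterally before deformation. Three ellipsoidal
intramuscular fat pockets (30–60 mm long, seeded placement) sit in the
muscle at least 20 mm clear of the bone, so that — as the segmentation
assumes — fat appears as separate short clusters rather than as
appendages of the bone cluster. The ground-truth axis is the deformed
marrow-centre line, fitted through mapped samples.

## Forward model

Linear (P1) tetrahedral FEM with the complete electrode model: finite
electrodes with contact impedance 100 Ω·cm², intra-electrode shunting, and
a common-ground boundary node that fixes the gauge (verified to leave the
original singular system satisfied to machine precision). Each electrode's
surface integrals are rescaled so its effective area equals the nominal
7 mm disc: the selected boundary faces only approximate the disc, and on
two different discretizations of the same phantom the raw face areas can
differ by ~50 %, which would make the two meshes model physically
different electrodes.

Drive patterns are the 16 opposite pairs `(i, i+8)`; measurements are the
12 adjacent non-driving pairs per pattern (192 total). The sensitivity
matrix uses the adjoint-field identity
`∂V_m/∂σ_e = −vol_e · ∇u_drive · ∇u_meas`, validated against finite
differences to ~10⁻⁵ relative.

## Data generation versus inversion (inverse-crime control)

`V1` (all tissues) and `V0` (boneless) are both simulated on the *fine*
mesh, so `ΔV` carries only tissue signal; the Jacobian and the
reconstruction live on an independently generated coarser mesh of the same
solid. This is the standard split — data model and inversion model are
different discretizations — and was chosen after measuring that computing
`V0` on the coarse mesh injects a discretization-difference artifact
several times larger than the configuration-2 bone signal.

## Reconstruction and its effective regularization

The published hyperparameter λ = 7·10⁻⁵ is retained, but at any plausible
unit convention the quadratic smoothness penalty it scales is orders of
magnitude weaker than the data term. Meanwhile the bone-versus-muscle
contrast is −95 %, far outside the linear regime, so an exact minimizer of
the linearized objective overfits linearization error into large-amplitude
artifacts. The effective regularizer is therefore the *truncated conjugate
gradient iteration* (semiconvergence): the default budget of 200
iterations was calibrated once on the cylinder verification phantoms and
then applied unchanged to the realistic models. Deeper iteration sharpens
the image but amplifies shell overshoot; shallower iteration blurs the
bone into the background band. `RegularizationConfig` exposes the budget,
tolerance, W-mode (identity or inverse-covariance) and an optional
non-zero prior mean.

## Segmentation

Electrode-proximal elements are removed before binning. The exclusion
radius is five electrode diameters (35 mm) around each electrode centroid:
the deep reconstruction spikes that would otherwise stretch the low-bin
range sit 26–35 mm from the centroids at the study mesh scale (the spec of
the binning presumes the bone is the most negative surviving structure).
The sorted remaining values are scanned for the flat background band with
a lag-100 slope threshold scaled by `N₀/N` (`N₀ = 230 000`); a
median-anchored line fit over the band gives the RMS half-width of the
dead band (bin 10), nine equal bins cover the values below it and five
above. Because every tissue contrast here is negative, the upper interval
can be empty; it is then kept as a zero-width sliver (bins above 10 are
never clustered). Clusters are grown by flood fill over face adjacency for
bins ≤ 7 (bin 8 is a deliberate guard gap) from ascending element ids, and
clusters smaller than 64 elements that touch the outer surface or an
electrode are discarded.

## Axis estimation

Per candidate cluster (ascending size): values outside mean ± 1.9 SD are
trimmed; the centroid and dominant right-singular vector give the initial
axis; the refinement minimizes the weighted orthogonal-distance objective
over spherical axis angles and the in-plane centre (the along-axis centre
component is a gauge freedom, pinned to the electrode plane), with
L-BFGS-B inside a trust region (±15° axis swing, ±5 cm centre shift) so
the local polish cannot leave the SVD basin.

The axial weight parabola of the published form has its apex *at* the
electrode plane and grows off-plane with `w²` ratios of ~10⁵ for a single
belt (the shift term `h` is tiny), letting a handful of far points own the
fit and — if the weights are recomputed from the current axis — creating a
degenerate attractor at horizontal orientations. The pipeline therefore
(a) freezes the weights at the initial axis and (b) defaults to the
inverted reading (off-plane difference values are less reliable, so
down-weight them) with a bounded 4:1 profile. The as-printed increasing
profile remains available (`invert_weights=False`).

Cluster selection: largest axial extent `Δζ` wins; candidates within 5 %
of the largest are tie-broken by lower mean `Δσ`, and near-identical means
fall through to the larger `Δσ` range.

## What the study shows, and does not

At the default reduced scale (≈64k / ≈27k elements; the published study
used ≈230k), with seeds 0–3:

* cylinder, homogeneous reference: refined position ≈ 0.4 mm — the
  verification target is met comfortably;
* realistic phantoms: initial positions 6–29 mm, refined angles ≈ 2–4°,
  with the homogeneous configuration's position dominated by the merged
  fat-shell smear.

The refined angular deviations settle around 2–4° rather than the ≤ 2.9°
worst case / ≈ 1.5° mean reported at full scale with a single
reconstruction model. We attribute the gap to the honest two-mesh setup
and the reduced mesh density: an explicit same-mesh diagnostic narrowed
but did not close it, and the forward solver, Jacobian and reconstruction
each verify against independent oracles (reciprocity ~10⁻¹⁵, finite
differences ~10⁻⁵, dense least squares ~10⁻¹¹).

The generator emulates geometry and conductivity structure only: no
measurement noise by default (a seeded additive-noise hook exists), no
electrode placement error, no contact-impedance variability, real
conductivity (no permittivity), and the boneless reference model is built
from the same known solid — in a clinical setting it would come from
imaging with its own registration error. Passing tests therefore bound
method error under idealized conditions, not performance on real limbs.

## Determinism

Meshes, solves and fits are fully deterministic; the seed affects only the
intramuscular-inclusion placement and optional measurement noise. Two runs
with the same configuration are bit-identical.
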