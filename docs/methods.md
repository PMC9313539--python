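# Methods

`spinequant` implements a dual-modality analysis of vertebral bone: (i)
CT-driven voxel finite-element estimation of vertebral failure load and
failure displacement under published HU–density–modulus–strength
relations, (ii) chemical-shift-encoded (CSE) water–fat MRI inversion for
proton-density fat fraction (PDFF) maps, and (iii) the nonparametric
cohort statistics that compare the two patient groups (diffuse
osteoblastic metastases vs. osteoporosis) and correlate PDFF with the FE
measures. Because raw patient images are not available, the pipeline is
exercised end-to-end on synthetic phantoms; the per-vertebra measurement
table of the seven-patient cohort ships as a packaged fixture and drives
the statistics stage exactly.

## Constitutive model (materials)

Per element, from the effective Hounsfield value `HU`:

```
rho_app [g/cm^3] = max( (47 + 1.122 HU)/1000 , 0.001 )
rho_ash          = 0.6 rho_app
E_z  = 4730 rho_app^1.56  [MPa]      E_x = E_y = 0.333 E_z
G_xy = 0.121 E_z                     G_xz = G_yz = 0.157 E_z
nu_xy = 0.381                        nu_xz = nu_yz = 0.104
sigma_max = 137 rho_ash^1.88 (rho_ash <= 0.317) ; 114 rho_ash^1.72 above
sigma_min = 65.1 rho_ash^1.93  [MPa]
eps_AB    = max(0, -0.00315 + 0.0728 rho_ash)
```

The linear HU calibration is published in kg/m^3; the power-law
coefficients and the 0.317 branch point are only dimensionally meaningful
in g/cm^3, so the linear relation is evaluated as printed and divided by
1000 before any power law. The density floor (0.001 g/cm^3, reached below
about −42 HU) keeps the power laws defined for fatty marrow and air; the
`eps_AB` clamp removes the negative strain limits the affine relation
would produce below 0.0433 g/cm^3 ash density. The branch point uses the
lower law at exactly 0.317; the two branches differ there by 0.003%, so
the composed strength law is continuous to well within 0.4% relative.

z is the superior–inferior axis; the transversely isotropic compliance is
filled with the loading-in-first-axis Poisson convention
(S_xz = −nu_xz / E_x) and is symmetric by construction. Positive
definiteness is checked per element.

### Element integration

Element HU is pooled per source *cell* (see meshing) over the voxels of
the segmentation mask, using modulus integration: apparent densities are
averaged under the E ∝ rho^1.56 law (power mean) and converted back to an
equivalent HU, so each element's axial modulus equals the volume average
of the voxel-wise moduli. Plain HU averaging is available
(`integration="hu"`) but carries a Jensen bias under the convex
density–modulus law that systematically stiffens coarse meshes. Boundary
treatment is mass-conserving: masked voxels of cells that fall below the
occupancy threshold are adopted by the nearest kept cell, and each
element's moduli and strength limits are scaled by its cell's masked
volume fraction (partial-volume homogenization). Together these make the
integrated stiffness and strength of the model independent of the chosen
cell size, which is what the mesh-convergence harness verifies.

## Meshing

The segmentation mask is aggregated into cubic cells whose side is the
nearest integer multiple of the voxel spacing to the requested edge
length. Cells at least 50% inside the mask are kept; each becomes six
tetrahedra by the Kuhn/Freudenthal subdivision with a globally fixed
diagonal, which makes shared faces conform by construction (verified:
every interior face appears exactly twice). Elements are oriented for
positive volume. The inferior/superior loading node sets are the nodes of
the lowest/highest occupied z-planes — adequate for axis-aligned
phantoms, not an anatomical endplate detector.

## Finite-element compression

Quasi-static, displacement-controlled: the inferior surface is fixed (a
`CompressionConfig` switch frees its in-plane translations; the effect on
the phantom failure loads is small — both variants are exercised in the
test suite), the superior surface receives a prescribed axial displacement
with free in-plane translation, ramped in `n_increments` (default 40)
steps to `max_displacement_frac` (default 2%) of the specimen height.

At each increment the element states iterate to a fixed point:

1. linear solve of the current secant system;
2. principal stresses per element; yield where `sigma_1 > sigma_max` or
   `sigma_3 < −sigma_min`;
3. yielded elements are scaled by the secant factor that caps the violated
   principal stress at its limit (scales only decrease);
4. an element whose accumulated post-yield axial strain exceeds its
   (regularized) `eps_AB` is killed: scale 1e-3, kept nonzero so the
   system stays positive definite.

The iteration converges when no state changes, or when the reaction force
is stable to 0.1% with no kill in the pass (secant micro-yield cascades
can otherwise churn for hundreds of passes without changing the
observable). If the cap (default 50) is hit clearly past the force peak,
the loading is ended as structural collapse — post-peak snap-through has
no quasi-static fixed point. Loading also stops when the force falls below
50% of the running peak (or, optionally, as soon as the failure point is
determined).

**Crack-band regularization.** Post-yield strain localizes into a band one
element high, so applying `eps_AB` directly makes failure displacement and
load proportional to the element size. The limit is therefore scaled by
`(2.0 mm / element size)`: the dissipated band displacement becomes
mesh-independent, with 2.0 mm — the converged element size of the
underlying study — as the reference at which the printed relation applies
unchanged.

**Linear solver.** Sparse Cholesky-like LU factorization; when element
scales change, the previous factorization preconditions a conjugate
gradient solve (relative tolerance 1e-10) and a fresh factorization is
computed only if CG stalls.

The failure point of the load–displacement curve is the first local force
maximum followed by a drop exceeding 1% of that maximum; a curve with no
such drop fails at its global maximum.

Verified closed forms: elastic slope `E·A/L` (exact with nu = 0 under any
support; within 2% with nu = 0.3 and frictionless supports), limit load
`sigma_min·A` within 5%, reaction reciprocity to 1e-6, six rigid-body
modes, linear scaling of failure load with a uniform scaling of moduli and
strengths.

## Water–fat signal model and PDFF

Per voxel, echo time `t` (s):

```
s(t) = (rho_W + rho_F · sum_p alpha_p e^{i 2π f_p t}) · e^{i 2π psi t} · e^{−R2* t}
```

with a seven-peak fat spectrum (relative amplitudes `alpha_p` summing to
1, frequency offsets `f_p` from the fat resonances at the scanner field
strength), field map `psi` (Hz) and a single `R2*` (1/s) shared by water
and fat. The default echo train is six echoes at TE = 1.12 + 0.96·k ms.
The shipped spectrum is a standard published bone-marrow triglyceride
spectrum (offsets 0.60 to −3.40 ppm relative to water); it is editable
configuration because generation and fitting must simply agree on it.

Fitting is voxel-independent VARPRO: for each candidate (psi, R2*) on a
grid (default psi −150..150 Hz step 2, R2* 0..300 step 25) the two complex
amplitudes are solved in closed form; the best candidate seeds a bounded
trust-region refinement of (psi, R2*). PDFF = 100·|rho_F| / (|rho_W| +
|rho_F|). The magnitude estimator is exact in the noiseless regime and
carries a small noise-floor bias (measured: ≲0.01 pp at SNR 50, far below
the 1 pp bound the acceptance check asserts). No spatial regularization of
the field map is used: the synthetic field maps are smooth and small, so
water–fat swaps are excluded by the grid bounds rather than by the
graph-cut machinery used on patient data. Per-vertebra PDFF is the mean
over the vertebra's fitted voxels (the conventional ROI statistic; the
underlying study does not state mean vs median).

## Synthetic data

**CT phantom** — an elliptic-cylindrical vertebral body (default semi-axes
14 × 11 mm, height 24 mm, 1 mm voxels) with a cortical shell (default
thickness 1.5 mm) and a stochastic trabecular interior, in −1000 HU air:
osteoporotic interior Normal(80, 30) HU with a 500 HU shell (cortical
thinning/porosity and partial-volume averaging lower the imaged cortex),
osteoblastic interior Normal(600, 150) HU with a 1200 HU sclerotic shell.
The trabecular noise field carries a spatial correlation length
(`texture_sigma_mm`, default 1.2 mm, marginal SD preserved): real
trabecular HU fields are smooth at the millimetre scale, and white
voxel-scale noise would make the weakest cross-section — and hence the
failure load — depend on how each mesh size happens to aggregate it. The
24 mm height is commensurate with both 1.5 and 2.0 mm cells so the
convergence pair meshes the same specimen height. An optional Gaussian
scanner-PSF blur is off by default. Not modelled: posterior elements,
endplate curvature, cortical porosity, fracture morphology — so the
absolute phantom failure loads are not patient-like; only their contrasts
and convergence behavior are meaningful.

**Echo series** — the forward signal model evaluated on PDFF/R2*/field
maps, with optional complex Gaussian noise of standard deviation
|s(TE1)|/SNR per voxel.

**Cohort tables** — per-vertebra values drawn from group-specific
log-normal distributions whose default medians are the published pooled
group medians (PDFF 11.9 vs 43.8%, failure displacement 0.874 vs
0.348 mm, failure load 29 589 vs 3 095 N), with a patient-level random
effect (log-SD 0.15) and per-vertebra scatter (log-SD 0.35/0.20/0.30 for
PDFF/displacement/load, chosen to echo the published within-group
scatter). An `effect_profile` of 0 collapses the groups onto a common
median for null-configuration testing.

**Fixture** — the seven-patient, four-level table of PDFF, failure
displacement and failure load, with the fracture flags reconstructed from
the clinical narrative (patient 4: L2+L3 vertebroplasty; patient 5: L4
endplate fracture; patient 6: L2 compression + L4 endplate fracture).
That reconstruction is validated by reproducing every per-patient
median/IQR cell.

## Statistics

Fractured vertebrae are excluded before any averaging or testing.
Quartiles interpolate order statistics at positions `1 + (n−1)p` — the
convention that reproduces the published brackets where others fail.
Group descriptives pool all non-fractured vertebrae; group tests run on
per-patient medians. Mann-Whitney U uses the asymptotic normal
approximation without continuity correction and tie-corrected variance —
the only variant that reproduces the published p = 0.034 for the fully
separated 3-vs-4 comparison (an exact test gives 0.057). Spearman's rho is
the Pearson correlation of average ranks with the t approximation on n−2
df and a Fisher-z 95% CI (SE 1/sqrt(n−3)). Friedman's test ranks levels
within patients, with tie correction; patients with incomplete level sets
after exclusion are dropped. Published-value comparisons round half away
from zero at the printed precision; because the printed per-vertebra
inputs are themselves rounded, interpolated quartiles can legitimately
differ from a printed bracket by up to one unit in the last digit, and the
regression harness uses exactly that tolerance (most cells agree to half a
digit; the published PDFF group p of 0.032 is not reproducible by any
U-test variant on the separated patient-level data and is reported as
0.034 here).

## Problem sizes

The harnesses run at desk scale: the convergence pair meshes a 0.5 mm
voxel phantom at 1.5/2.0 mm (≈21 k / 9 k tetrahedra, 120 displacement
increments to 0.15 mm with early stop — fine enough to resolve the force
peak to ~2% of the failure load, which the default 40-step schedule would
alias), the group-contrast pair a 1 mm voxel phantom at 2.0 mm (≈9 k
tetrahedra, default schedule), and the PDFF Monte-Carlo uses 500 draws at
SNR 50.

## Known limitations

- The exact plasticity model of the commercial solver used in the source
  study is not replicated; the secant/kill realization is standard for
  validated QCT-FEA but not identical, so absolute failure values differ.
- Failure displacement inherits the quantization of the displacement
  increments.
- Linear tetrahedra are over-stiff in bending-dominated regimes; the
  phantom load cases are compression-dominated.
- The per-voxel PDFF fit ignores spatial coupling, T1 bias and
  multi-compartment R2*; accuracy statements hold for the synthetic
  generator's signal model, not for patient data.
- The cohort generator draws independent log-normals; it does not emulate
  the within-patient level correlation structure beyond a patient-level
  shift, nor fracture-induced outliers.
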