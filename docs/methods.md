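# Methods

`hemoline` reproduces, at desk scale, a complete surrogate-modelling workflow
for aortic-stenosis hemodynamics: spatially resolved static pressure and wall
shear stress (WSS) along the aortic centerline are predicted by a
bi-directional LSTM from geometry and flow-rate features, and the prediction
is evaluated against a reference solver with the field's standard accuracy
metrics and a statistical equivalence test on the transvalvular pressure
gradient (TPG). Because no clinical CT/CFD data ships with the package, two
synthetic components close the loop: a parametric geometry generator and a
reduced-order physics oracle that stands in for 3D CFD.

## Compact centerline representation

All quantities live on a discrete centerline with 2 mm point spacing
(typically 110–130 points per case). Per point:

- a cross-section plane orthogonal to the local tangent (central
  differences; one-sided at the ends). In-plane axes are parallel-transported
  (rotation-minimizing frame), so cross-section rasters do not spin as the
  curve sweeps the arch. The resampler steps by *chordal* distance, so
  consecutive points are exactly 2 mm apart even on curved segments.
- averaged static pressure `P_i` (mmHg): the arithmetic sample mean over the
  plane. In the valve region only the leaflet-bounded orifice contributes.
  Averaging is sample-mean, not area-weighted (the convention is a package
  choice; the two coincide for uniform sampling).
- averaged WSS `WSS_i` (Pa): mean wall-sample magnitude over the vessel
  segment between planes i and i+1, assigned to point i; the last point
  repeats the last segment so sequences keep length N. Valve segments use
  leaflet-surface samples only.
- a binary 68×68 raster of the lumen polygon over a fixed 50 mm physical
  window. A fixed window (rather than per-section normalization) preserves
  absolute size, so the shape code carries more than scale.

## Synthetic geometry generator

Cases are candy-cane tubes: straight LVOT/valve/ascending limb, semicircular
arch, straight descending limb, with segment length fractions
LVOT 10 / valve 5 / ascending 30 / arch 25 / descending 30 % of the total
length. Cross-sections are mildly elliptic (area-preserving jitter,
SD 0.03, seeded per case); the valve region carries an `n_leaflets`-fold
"tri-star" orifice polygon scaled so its area equals the prescribed aortic
valve area (AVA) to float precision. Polygons are rescaled so their shoelace
area equals the analytic lumen area exactly.

Default cohort ranges (uniform sampling): AVA 0.4–2.0 cm² (severe stenosis
through healthy), LVOT diameter 20–24 mm, ascending 26–32 mm, descending
21–27 mm, total length 222–258 mm. Two constraints shaped these ranges: the
total length keeps `floor(L/2)+1` within 110–130 points, and the ascending
radius stays below the arch curvature radius (~18 mm at the shortest
lengths) so the lofted tube cannot fold through itself. Cohort diameters are
literature-plausible defaults, not fitted to any patient population.

Lumen radius blends between segment plateaus with smoothstep ramps; the
valve exit uses an ease-out ramp (maximum slope at the orifice lip) so the
jet expands immediately downstream of the valve and the pressure minimum
stays at the orifice — without this the first post-valve point combines
orifice-level velocity with accrued expansion loss and becomes a spurious
minimum.

## Reduced-order physics oracle

A quasi-1D extended-Bernoulli march replaces 3D CFD. With flow rate Q and
per-point lumen area `A_i` (effective area `cc·A_i` inside the valve,
contraction coefficient cc = 0.85):

- `V_i = Q / A_eff,i`; the throat velocity is the vena-contracta velocity.
- pressure: `P_i = P_1 + ½ρ(V_1² − V_i²) − F_i − B_i`, where `F_i`
  accumulates Darcy friction (f = 64/Re for Re < 2300, Blasius
  0.316 Re^−0.25 above) and `B_i` is a Borda–Carnot expansion loss
  `K·½ρ(V_vc − V_ds)²` (K = 1) ramped linearly over a 40 mm recovery length
  downstream of the point where the lumen actually re-expands. The ramp
  start is detected from the area profile (trailing orifice-area points are
  treated as part of the orifice), not from the region label.
- WSS: `(f/8)·ρ·V_i²` plus a jet term `g·½ρV_vc²·exp(−(s−s_vc)/L_rec)` with
  gain g = 0.02 applied from the throat onward — including the late-valve
  points, which keeps the global WSS peak inside the valve region for
  stenotic cases while still producing the decaying elevated WSS where the
  jet impinges downstream.
- profiles are shifted by a constant so the outlet reads exactly 130 mmHg
  (incompressible flow is invariant to the absolute level; differences are
  preserved to machine precision).

Physical constants: ρ = 1050 kg/m³, μ = 0.0035 Pa·s (constant,
infinite-shear value; shear-thinning rheology is out of scope). Pressure is
mmHg on every public surface (1 mmHg = 133.322 Pa), WSS is Pa, flow ml/s —
note ml/s ÷ mm² = m/s exactly, which the feature builder exploits.
`include_friction=False` switches off viscous losses for inviscid checks
(pure quadratic scaling in Q). WSS magnitudes are plausibility-scaled
synthetic values; no quantitative WSS-geometry law is claimed.

Derived scalars: MPD = `P_1 − min_i P_i` (maximum pressure drop);
TPG = `P_1 − max{P_i : i > argmin P}` (pressure at the highest recovery
point downstream of the minimum; the search spans the entire downstream
profile). If the minimum sits on the last point the inlet-to-outlet drop is
returned with a warning. TPG ≤ MPD holds by construction.

Field samples (the stand-in for 3D CFD fields) scatter per-plane pressure
values with spread 0.05·½ρV² (as mmHg) and per-segment wall WSS values with
a von-Mises circumferential asymmetry (κ = 1) downstream of the valve. The
noise is re-centred exactly, so averaging recovers the profile to machine
precision and round-trip tests are deterministic; what the samples exercise
is the valve-masking and segment-assignment logic, not estimator variance.

## Dataset assembly

- Baseline flows come from an AVA-shifted truncated normal:
  mean 150 + 250·AVA ml/s, SD 15 % of the mean, truncated to [100, 700]
  ml/s. (Observed flows can be passed through instead.)
- Each geometry is augmented with −25 % and +25 % flow variants, re-solved
  by the oracle: a 103-geometry cohort yields 309 records.
- Records with MPD > 120 mmHg are removed (boundary inclusive: 120.0 is
  retained, matching the reading that cases *in excess of* the bound were
  unphysiological). Under the default cohort this drops roughly a quarter
  to a third of the records, concentrated at small AVA and +25 % flow.
- The retained records are split into 11 subsets (1 test, 10 for
  training/validation) by sorting geometries on baseline MPD with a seeded
  tie-shuffle and dealing round-robin — every subset then spans the MPD
  range, and all flow variants of a geometry stay together, so held-out
  geometries are never seen during training in any flow condition.

Features per centerline point: pose-normalized coordinates (inlet at the
origin, initial tangent along +z, arch plane in x–z), cross-section area
(mm²), area-normalized flow Q/A (m/s), and the m = 4 autoencoder shape code
— a 9-wide row. Features and both target channels are z-scored with
statistics fitted on the training subsets only; constant columns are guarded
(scale 1) and remembered so perturbation analyses treat them as zero-SD.

## Shape autoencoder

A single-hidden-layer autoencoder (sigmoid encoder and decoder, MSE loss,
minibatch Adam, seeded) maps flattened 68×68 rasters to m = 4 codes. The
decoder bias is initialized to the logit of the per-pixel mean occupancy;
starting from the corpus mean image instead of uniform grey speeds
convergence on mostly-empty binary rasters by an order of magnitude. No
sparsity or weight regularization is applied by default. The AE trains on
all cross-sections (vessel and valve) pooled over training geometries,
sub-sampled to at most 3000 images. Binary metrics threshold
reconstructions at 0.5; quality is reported as pixel-count IoU.

## Bi-LSTM surrogate

Two LSTM directions (gate order i, f, g, o; forget bias 1) process the
feature sequence forward and backward (the reverse pass reverses each
sequence within its own length); their hidden states are concatenated and a
per-point head (tanh layer, then linear) emits standardized pressure and
WSS. Training minimizes masked MSE equally weighted over both z-scored
channels with Adam (lr 3e-3, batch 32, 300 epochs, gradient-norm clip 1.0);
padded points contribute zero loss, so any sequence length works without
retraining. Networks are NumPy throughout; analytic BPTT gradients are
verified against central finite differences in the test suite. Predicted
WSS is floored at zero after de-standardization.

The reference configuration is hidden 900 with a 200-unit head; the desk
default (hidden 64, head 32) trains in ~3–4 minutes on one CPU at the
benchmark size and is what tests and examples use. k-fold cross-validation
rotates over the non-test subsets; grid search selects the configuration
with minimal mean combined validation RMSE (channels combined on the
training target scales), ties broken toward fewer parameters, then grid
order.

## Evaluation

Per case: `RMSE_P = sqrt(mean((P^pred − P^ref)²))`;
`NRMSE_P` divides each residual by `P_1^ref − inf P^ref` inside the RMS (the
printed per-residual form — equal to RMSE/MPD since the denominator is
constant per case, an equality the tests assert); `NRMSE_WSS` divides by
`sup WSS^ref`. Undefined denominators (no pressure drop, all-zero WSS)
raise rather than return infinities.

TOST equivalence of TPG: with paired differences `d_j = TPG_ref − TPG_pred`,
the two one-sided hypotheses (median difference below −ε, above +ε;
ε = 5 mmHg, the accuracy of catheter-based pressure measurement) are tested
with Wilcoxon signed-rank tests on `d + ε` and `d − ε`; equivalence is
declared iff both p < α (α = 0.05 — the package default, chosen since only
p-values are conventionally reported). The exact null distribution is used
for n ≤ 25 without zeros; zeros fall back to Pratt's method under the
tie-corrected normal approximation.

Cohort summaries report medians and IQRs (linear-interpolation quantiles),
Pearson correlations of pressure RMSE vs reference MPD and WSS RMSE vs
reference peak WSS, a Wilcoxon rank-sum comparison of test-subset MPDs
against the cohort, and a Lilliefors normality test (via statsmodels) on the
WSS RMSE distribution.

Explainability: a feature column is shifted by ±1 training SD over points
`[i−w, i+w]` (default half-width 3 points = 6 mm — "local" on a 2 mm grid)
and the RMSE between perturbed and unperturbed predictions is averaged over
the two signs, per output channel. Zero-SD (constant) features return
exactly zero.

## What the synthetic benchmark does and does not show

The desk benchmark (100 geometries × 3 flows, MPD-filtered, 11-subset
split, desk-size network) verifies that the entire pipeline — shape
encoding, sequence model, standardization, grouped splitting, metrics,
equivalence testing — can recover a nonlinear reference hemodynamics model
from its own features, with held-out median NRMSE of a few percent for both
channels and TPG equivalence inside ±5 mmHg. It does not show clinical
accuracy: the oracle is smooth, fully determined by the features, and free
of segmentation error, imaging noise, turbulence and patient variability,
so real-data errors will be larger. Cohort accuracy numbers from clinical
CFD datasets are correspondingly out of scope.

## Numerical choices and degenerate inputs

- One global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence.spawn`; every stage is reproducible in
  isolation and all derived seeds stay below 2³¹.
- Grid-search ties: fewer parameters, then grid order. Signed-rank zeros:
  Pratt. Quantiles: linear interpolation. Raster occupancy: pixel-centre
  inside polygon.
- Degenerate inputs raise typed errors: empty profiles, zero lumen areas,
  non-positive flows, empty sample sets, curve shorter than two spacings,
  boundary exceeding the raster window, mismatched feature widths,
  sub-minimal cohort sizes.
- The geometry build rejects lumens whose radius reaches the arch curvature
  radius (fold-over). Degenerate straight-tube cases (single region, no
  valve) skip contraction, expansion-loss and jet terms entirely.

## Known limitations

- The centerline is planar; real aortas are non-planar, so the y-coordinate
  feature is constant under the default generator (and guarded in
  standardization).
- The oracle has no turbulence, unsteadiness, fluid–structure interaction
  or non-Newtonian rheology; its WSS level is synthetic by construction.
- User-supplied surface meshes must come with a centerline; skeletonization
  is not implemented.
- The AE code space saturates (sigmoid codes near 0/1) at the extremes of
  the trained size range; codes are most informative for shapes inside the
  training distribution.
- Branching vessels are not represented.
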