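# Methods

`tumortwin` builds a patient-specific ("digital twin") model of breast
tumor response to neoadjuvant A/C chemotherapy from longitudinal
quantitative MRI, and uses it to design alternative dosing schedules.
This note documents the model, the numerical choices, and the limits of
what the synthetic-data experiments can show.

## Imaging model

Diffusion-weighted MRI provides an apparent diffusion coefficient (ADC)
map per visit; cellularity is assumed to scale linearly with the ADC
deficit relative to free water,

    N(x) = theta * (ADC_w - ADC(x)) / (ADC_w - ADC_min),

clipped to `[0, theta]` inside the tumor segmentation and zero outside.
`theta` is the physical carrying capacity per voxel: voxel volume times
the densest sphere-packing fraction (0.7405) divided by the volume of a
10 µm spherical cell.  `ADC_w` defaults to 3.0e-3 mm²/s (free water at
body temperature) and `ADC_min` is the minimum ADC observed inside the
tumor segmentations across visits.  Local drug delivery is summarized by
the area under the dynamic contrast-enhancement curve (AUC), min–max
normalized to [0, 1] over the breast mask.

Tumor *volume* needs an occupancy threshold that imaging alone does not
define; a voxel counts toward volume when its cellularity reaches 1% of
`theta` (configurable).  This includes all meaningfully occupied voxels
while excluding the numerical-diffusion halo of the simulation.

## Growth–response model

Normalized cellularity `n = N/theta` obeys a Fisher–Kolmogorov equation
with a chemotherapy kill term on the breast-masked voxel grid:

    dn/dt = D lap(n) + k(x) n (1 - n) - n * sum_j gamma_j(x, t)
    gamma_j(x, t) = alpha * sum_k AUC_k(x) C_{j,k} 1[C_{j,k} >= 0.1]
                    1[t >= tau_{j,k}] exp(-beta_j (t - tau_{j,k}))

with diffusivity `D` (mm²/day), spatially resolved proliferation `k(x)`
(1/day), drug efficacy `alpha` (1/day), and per-drug decay rates
`beta_j` (1/day; j ∈ {Adriamycin, cyclophosphamide}).  Doses are in
normalized units (NU, 1 NU = the drug's maximum tolerated dose); doses
below 0.1 NU are not recognized as deliveries and are zeroed when a
regimen is canonicalized, so dose accounting, risk functionals and the
kill term all see the same effective schedule.  A delivery is active
from its delivery instant (`1[t >= tau]`, with equality included).
Each delivery's AUC map is the most recent imaging visit's map on or
before the delivery day.

Discretization: second-order central differences with zero-flux
boundaries at the breast-mask edge (out-of-mask fluxes dropped), forward
Euler in time.  Numerical choices that matter:

* **Step size.**  `dt = min(0.025 day, diffusive CFL, 0.5/(k_max + alpha))`.
  With millimetre voxels the CFL bound is never active; the 0.025-day cap
  is accuracy-driven — halving it moves the reference bulk-cell
  trajectory by ~0.3%, so the first-order scheme is inside its
  convergent regime through the fast kill pulses.
* **Step-averaged kill weights.**  The cyclophosphamide decay
  (`beta_C` up to 5.5/day) is fast on the Euler step; sampling the decay
  factor at the left endpoint over-integrates every pulse by
  O(`beta dt`/2) (≈5% in bulk cells at dt = 0.1).  The scalar decay
  weight of each delivery is therefore replaced by its exact average
  over the step; the full- and reduced-order solvers use the identical
  rule, preserving their equivalence at full rank.
* **Clipping.**  The full-order state is clipped to [0, 1] after each
  step (explicit overshoot guard).  Reduced states are not clipped
  during integration (bounds are not representable in the reduced
  coordinates); lifted fields are clipped for reporting.

## Reduced-order model

Snapshots are built from the two calibration visits: `n_pseudo = 8`
linear interpolations in pseudo-time between V1 and V2, each augmented
with mask-aware Gaussian-smoothed copies at widths {1, 2} voxels.  The
SVD of the snapshot matrix, truncated at 99.5% cumulative squared
singular-value energy, gives the orthonormal basis `V`.  All model
operators are Galerkin-projected onto span(V); because each operator is
affine in its parameter (diffusion linear in D, the proliferation
operators linear in each Karhunen–Loève coefficient of `k`, the
treatment term a scalar weight times a fixed projected AUC operator),
unit operators are projected once and recombined exactly at simulation
time — no operator interpolation over a parameter grid is needed.  The
proliferation field is reduced on the same basis (`k ≈ V k_r`), with
per-coefficient prior bounds estimated by projecting 200 random fields
uniform in the per-voxel box [1e-6, 0.1]/day plus the two constant
extremes.

**Fidelity.**  At full rank the reduced model reproduces the full solver
to machine precision (the core correctness oracle, exercised on a
6×6×1 grid).  At the 99.5% truncation of two-visit snapshot data the
basis typically has rank 3–4, and the reduced trajectory deviates from
the full-order one by tens of percent in bulk cells over a 56-day
treatment horizon.  This is not an implementation artifact: the
l2-optimal projection of the full-order trajectory onto the rank-3 basis
already carries a ~20% bulk-cell error, a floor no Galerkin scheme can
beat, and the closure error of the truncated nonlinear dynamics
compounds on top of it.  The calibration is insulated from this because
the tolerance (below) is set by the reduced model's own best achievable
misfit; predictions and optimization comparisons are made consistently
within the reduced model.  Conclusions transferred to the full-order
model should be re-checked with full-order simulations.

## Calibration

The unknown is `theta = (D, k_r, alpha, beta_A, beta_C)`.  Priors encode
identifiability: `D ~ TN(0.5e-4, 2.5e-4; 1e-6, 1e-3)`,
`beta_A ~ TN(0.60, 0.06; 0.35, 0.85)`,
`beta_C ~ TN(3.25, 0.56; 1.00, 5.50)` (informative, from
pharmacokinetic literature; these parameters are not identifiable from
two visits), `alpha ~ U(1e-6, 1)` and `k_r,i` uniform over the
Karhunen–Loève bound estimates (identifiable).

The distance is the mean squared error between simulated and measured
reduced states at the second visit, with V1 as the initial condition.
The tolerance epsilon is set to the misfit of a multistart (4 seeded
starts) box-constrained least-squares point fit, run in a
sigmoid-transformed unconstrained space.  Two well-posedness safeguards:

* Because the parameter vector has four more degrees of freedom than the
  reduced V2 residual, the point fit can interpolate the data
  essentially exactly, collapsing epsilon to the solver floor and the
  acceptance region to vanishing prior measure.  Epsilon is therefore
  floored at 1e-3 of the mean squared reduced data.  The posterior is
  insensitive to this floor: tightening it by two further decades leaves
  the marginals statistically unchanged.
* Plain rejection sampling from the priors accepts essentially nothing
  at such tolerances (0 of 20,000 prior draws within 3× epsilon on the
  reference patient).  `abc_rejection` implements the literal
  accept-if-below-epsilon rule and aborts, per its contract, when the
  acceptance rate falls below 1e-4; the pipeline's default sampler is
  sequential ABC (population Monte Carlo): a ladder of tolerances
  (median-of-distances annealing) ending at the target epsilon, with a
  full-covariance Gaussian perturbation kernel at twice the weighted
  population covariance.  The full covariance matters: the acceptance
  region is a thin curved manifold and a diagonal kernel stalls roughly
  two decades earlier.

The calibrated digital state is 500 accepted parameter vectors.  On
zero-noise synthetic responders the posterior shows the expected
identifiability split — `D`, `beta_A`, `beta_C` return their priors
while `alpha` and `k_r` contract — but `alpha`'s contraction is modest
(posterior SD ≈ 0.7× prior SD): with rank-3 reduced data and two
effective deliveries in the calibration window, a uniform shift of the
proliferation level inside its wide prior box can compensate a
substantial range of kill strengths.  The 95% credible interval covers
the ground truth.  Richer spatial data (higher basis rank) or more
deliveries between visits would tighten it.

## Risk functionals

Per drug, three quantities: total delivered dose (exact); the maximum
concentration, max over time of the pointwise median (across posterior
beta samples) of `c(t) = sum_k C_k 1[t>=tau_k] exp(-beta (t-tau_k))`;
and a toxicity surrogate that integrates, over every putative toxic
threshold lambda in (0, 1], the time spent above lambda — the
threshold is marginalized because the patient's LD50 is unknown.  For a
single unit dose the integral is 1/beta exactly (day·NU).

Numerics: concentration curves on a 0.01-day grid extending 8/beta past
the last delivery (a 5/beta horizon truncates 0.67% of the single-dose
integral); exceedance times counted at staggered midpoints (node
counting overstates each crossing by ~dt/2); the lambda integral uses
panel-wise logarithmic interpolation with an analytic log tail below the
first positive node, which is horizon-independent and matches the
closed forms to <0.5% on a 101-point lambda grid.  Scalar summaries
take the median across posterior samples first (then max/integral);
per-sample values are kept as distributions for rank-based tests.

## Regimen optimization

The twin is built after two delivered cycles; those stay fixed at 1 NU.
The decision variable is a daily dose vector over the third cycle's
window (length `delta_tau = tau4 - tau3`), mirrored identically onto the
fourth cycle, shared by both drugs.  Deliveries are on the daily grid;
a day is switched off by driving its dose below the 0.1 NU recognition
threshold, so times are not separate unknowns.  The horizon is
`t_f = tau4 + delta_tau`.

* **P1 (burden):** minimize median final cells plus the max of the
  median cell time course, each normalized by its standard-of-care (SOC)
  value (the SOC embedding scores exactly 2.0), subject to per-drug caps
  on total dose, maximum concentration, and toxicity at their SOC
  values.
* **P2 (dose):** minimize total dose (normalized) plus the normalized
  max of the median cell course, subject to the concentration and
  toxicity caps and non-inferior median final cells.

Constraints are normalized by their SOC values (dimensionless slacks,
feasibility tolerance 1e-6); risk quantities are evaluated from the
third cycle onward, the window the optimizer controls.  During
optimization the ensemble is subsampled (default 100 of 500, fixed
seed) and the risk grids are coarsened (0.05-day concentration step,
51 lambda nodes); the final report re-simulates both regimens on the
full ensemble at full precision and attaches one-sided Mann–Whitney
U-tests (direction: optimized lower).

The search is a multistart around COBYLA (derivative-free linear
approximation with constraints): a structured start set — the SOC
embedding, delayed single doses, and equal splits over the first days
of the window — is screened, the best feasible starts are polished
locally, and basin-hopping perturbs around the incumbent.  The
structured starts matter: the landscape has plateaus created by the
dose-recognition threshold, and moving a full dose to a later day
passes through worse intermediate schedules, so a single local search
from the SOC stalls there.  The SOC embedding always participates, so
the returned optimum is never worse than the delivered regimen; the
incumbent is the best feasible point ever evaluated.  With the decay
kill kinetics, gains on the synthetic responder come mainly from
delaying the mirrored dose within each cycle (less regrowth time after
the last kill before `t_f`), worth a few percent of final cells —
smaller than effects reported for clinical patients, whose calibrated
dynamics differ.

## Statistics

Concordance correlation (CCC) uses population (1/n) moments,
`2 cov / (var_x + var_y + (mean_x - mean_y)^2)`; for the hand example
x=(1,2,3), y=(1,2,4) the exact value is 6/7 (27/31 with the
sample-moment flag).  When each subject contributes a distribution, the
CCC is resampled (default 10,000 draws, one value per subject per axis
per draw) and reported as mean ± SD.  Mann–Whitney U-tests use exact
enumeration for small tie-free samples and the tie-corrected normal
approximation otherwise; one-sided directions are fixed per quantity
(reduction in cells/volume/dose/concentration/toxicity is "better").
Bootstrap Pearson regression draws one value per subject per iteration
and reports mean r with a percentile CI.  No multiple-testing
correction is applied; p-values are reported raw, per quantity.

## Synthetic patients

Clinical multi-visit breast MRI of this kind is confidential, so the
package ships a virtual-patient generator: an ellipsoidal breast mask on
a 32×32×16 grid at 2×2×4 mm (a sub-sampled breast region sized so a
full calibrate-and-optimize run takes minutes), an ellipsoidal tumor of
~8 mm radius seeded with a Gaussian cellularity bump (peak 0.75 of
capacity), a Gaussian-filtered random proliferation field rescaled to
[0.01, 0.06]/day, and per-visit AUC maps built from smooth random
fields blended with a tumor-centred kernel (perfused tumor sees more
drug), min–max normalized.  Ground-truth dynamics are simulated with
the full-order solver under a 4-cycle, 14-day A/C schedule with visits
at days 0, 28 and 56; ADC maps are produced by inverting the linear
ADC–cellularity relation, optionally corrupted with additive Gaussian
noise (default SD 5% of the ADC dynamic range — measurement noise is
not quantified in the imaging protocol, so this is a round number in
the plausible range) and clipped back to the physical ADC interval.
Two stock phenotypes mirror the clinical response split: a responder
(alpha = 0.5/day, shrinking under treatment) and a non-responder
(alpha ≈ 0, growth throughout).  Diffusivity (1e-4 mm²/day) and decay
rates (prior central values) are fixed mid-prior.

What these experiments do **not** emulate: registration error between
visits, Rician MRI noise physics, partial-volume effects at the tumor
rim, DCE pharmacokinetics (the AUC maps are synthetic surrogates), or
anatomically realistic breast geometry.  Passing tests on virtual
patients therefore demonstrate the *self-consistency* of the pipeline —
parameter recovery, identifiability structure, constraint handling —
not clinical accuracy.

## Known limitations

* The 99.5%-energy reduced model is a coarse dynamical surrogate at the
  basis ranks two-visit data support (see Fidelity above).
* Drug efficacy is only weakly identified from two visits; the
  posterior credible interval is honest but wide.
* Optimized regimens are ranked by the same reduced twin that was
  calibrated — there is no independent validation visit for regimens
  that were never delivered.
* The toxicity surrogate is a threshold-marginalized exposure time, not
  a mechanistic hematological model; absolute toxicity units are only
  comparable within a patient.
* Plain rejection ABC at the point-fit tolerance is not viable (see
  Calibration); the sequential sampler is required at realistic
  tolerances.
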