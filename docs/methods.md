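# Methods

This note documents the models, numerical choices and limitations behind
`gammaplan`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dose engine (`gammaplan.beam`)

**Kernel model.** A shot is modelled as a spherically symmetric dose kernel
centered on its isocenter: full-arc rotational delivery averages the beam
directions over a sphere, so the azimuthal structure of individual source
channels is ignored. Dose from a shot with weight `w` is
`w · TMR(depth) · P_c(r)`, with `r` the Euclidean distance from the
isocenter in mm. Depth is evaluated once, at the shot center, inside a
spherical water-equivalent head phantom (radius 80 mm) centered on the dose
grid; per-voxel depth variation across a kernel changes doses by well under
1% at these geometries and is omitted. There are no heterogeneity
corrections and no absolute dosimetry — all doses are relative, which is
sufficient because every index is defined through the 50%-of-maximum
prescription level and is therefore invariant under global rescaling (a
property the tests check end to end).

**Synthetic beam tables.** Measured commissioning data for gamma units are
proprietary, so the package generates synthetic tables and ships one fixture
(`src/gammaplan/data/beam/`). The radial profile of a collimator of nominal
size `s` is a rescaled logistic

    P(r) = σ((r0 − r)/a) / σ(r0/a),   a = penumbra / (2 ln 4),

where the shoulder `r0 = a·ln(exp(s/(2a)) − 2)` is solved in closed form so
that `P(0) = 1` and `P(s/2) = 1/2` exactly: the 50% isodose radius of a unit
shot equals the nominal collimator radius (the tests require agreement
within half a voxel). A plain logistic centered at `s/2` violates that
identity once the penumbra is comparable to the aperture radius, which is
why the shifted form is used.

* Collimator set: 4, 8, 14, 18 mm (a typical four-aperture gamma-unit set;
  configurable).
* Penumbra (80%–20%): 4.0 mm default. Measured gamma-unit profiles have
  soft shoulders — small apertures are nearly Gaussian — and profile
  softness matters physically: overlapping very flat-topped shots nearly
  doubles the peak dose midway between them, which under 50% renormalisation
  makes multi-shot packing impossible. 4 mm reproduces the qualitative
  packing behaviour of clinical units across the 0.5–10 cc range.
* TMR: `exp(−0.004·d)` on d ∈ [0, 160] mm, i.e. ≈0.4%/mm attenuation,
  representative of Co-60 beyond the build-up region.
* Table steps: 0.25 mm in radius (out to 25 mm, beyond which kernels are
  exactly zero), 1 mm in depth. Lookups interpolate linearly.

Kernels are pre-sampled per (collimator, grid spacing) and cached; plan dose
is the pointwise sum of pasted kernels in float32. Linearity identities
(additivity, homogeneity) hold to float32 rounding (~1e−6 relative), and
exactly for power-of-two weight scalings.

## Plan-quality metrics (`gammaplan.metrics`)

Volumes are voxel counts × spacing³ (reported in cc). Coverage, selectivity,
spill and DVHs are exhaustive voxel counts, checked against brute-force
oracles on random fields. `CI_RTOG = Cov/SI` and `CI_Paddick = Cov·SI`, so
`CI_RTOG · CI_Paddick = Cov²` identically; with an empty prescription
isodose volume, selectivity is defined as 0 and the CIs are undefined
(reported as 0 by `evaluate_plan` for the empty plan only).

**Rounding for published-table replication.** Clinical tables round half
away from zero at printed precision. Reproducing them from printed inputs
must be done in decimal: 0.98/0.80 = 1.225 exactly, which rounds to 1.23,
but its nearest binary double is 1.2249999…, which rounds to 1.22.
`conformity_indices(..., decimals=2)` therefore computes through
`decimal.Decimal` on the inputs' shortest repr. With that convention all 30
coverage/selectivity → CI pairs in the packaged validation table reproduce
exactly.

**Cohort comparison.** `compare_cohorts` applies a two-sided paired t-test
per index. Zero-variance difference vectors are flagged `degenerate`
(p = 1.0 when the differences are identically zero). A t-test on ~15 paired
cases agrees with a sign-flip permutation test to within a few hundredths,
which the suite verifies by Monte-Carlo oracle.

## Planning environment (`gammaplan.env`)

The observation is four binary channels on the case grid: state0 = target
minus current 50% isodose region (the feasibility mask and the only legal
shot positions), state1 = the isodose region, state2 = OAR union (context
only — no OAR term enters the reward), state3 = isodose region outside the
target. Three set identities (`state0 ∩ state1 = ∅`,
`state0 ∪ (state1 ∩ PTV) = PTV`, `state3 = state1 \ PTV`) are asserted
after every step of every test episode.

The per-step reward is `w_cov·ΔCov + w_si·ΔSI − w_spill·spill`, defaults
(1.0, 1.0, 0.5), with `spill = 1 − SI` (fraction of PIV outside the target;
a config switch makes it target-relative instead). The spill term uses the
*current* spill, not its increment, so persistent spillage is penalised at
every step. Episodes terminate at coverage ≥ 0.95 and selectivity ≥ 0.80
(typical clinical thresholds), on full coverage (empty feasibility mask), or
at 30 shots. The prescription level is recomputed after every shot — the
prescription rides the 50% isodose of the evolving plan, which is what makes
shot placement non-trivially sequential: every new shot can shrink the
isodose region of its predecessors.

An action is the joint choice (collimator, position), position restricted to
state0. Shot weight at placement is a single level 1.0 (a discrete weight
set is configurable); weighting is handled by post-hoc refinement in the
planner.

## Agent (`gammaplan.nets`, `gammaplan.ppo`)

Actor: four 3D convolutions (kernel 3, stride 1, padding 1), ReLU between,
the last layer emitting one score map per collimator; a softmax over all
(collimator, voxel) pairs with additive −1e9 on infeasible entries yields
exact zeros for masked actions while keeping log-probabilities finite.
Critic: four convolutions, global average pool, linear head to one scalar.
Hidden width defaults to 4 channels — the architecture's depth and kernel
geometry are fixed, but the width is chosen so a full per-case training run
is practical on a single CPU core; widths are configurable.

The networks, their backward passes, and Adam are implemented in numpy with
the convolution inner loops JIT-compiled by numba (float32 throughout,
deterministic given a seed). The analytic gradients of the clipped
surrogate, entropy bonus and critic MSE are verified against central finite
differences on small networks.

PPO follows the standard clipped form: advantage = discounted episode
return − value estimate (no GAE), ratio against the behaviour-policy
log-probabilities recorded at collection, loss
`−E[min(rA, clip(r, 1±ε)A)] + 0.5·MSE − 0.01·H`. Defaults: lr 0.003,
γ 0.99, ε 0.2, 5 epochs per update over shuffled batches of 8, entropy
coefficient 0.01 (set 0 for the bare actor/critic objective), advantage
normalisation off. One update runs after each episode on that episode's
transitions; memory is cleared afterwards.

**Policy field of view.** Dose and metrics live on the full working grid,
but the networks observe a window: the target bounding box plus 4 mm of
context. Legal actions all lie inside the target, and beyond a few
millimetres from it the state channels are almost always zero, so the wider
context is uninformative; the window cuts per-update cost by roughly the
volume ratio. The window is a planner parameter (`policy_context_mm`).

## Planner (`gammaplan.planner`)

`plan_case` crops the case to the target bounding box + 12 mm margin
(capped at 40 voxels per axis), trains a fresh agent, and after each episode
refines the final plan's weights and scores it: plans meeting the
termination criteria rank by Paddick CI and dominate plans that do not,
which rank by (coverage, Paddick CI). The best-scoring plan over training is
returned — training is a stochastic search and the incumbent best is the
usable artefact. The 12 mm crop margin contains the prescription isodose
region of any legal shot (largest 50% radius 9 mm plus penumbra).

**Weight refinement** (`optimize_weights`) is coordinate ascent over a
discrete weight grid {0.25, …, 2.0}, maximising Paddick CI subject to the
coverage threshold when attainable, at most 3 sweeps, accepting only strict
improvements (hence idempotent and never score-decreasing). Ascent runs from
two starts and keeps the better result: the plan's current weights, and
peak-balanced weights that iteratively equalise per-shot center doses.
Peak balancing matters because uneven peaks inflate the 50%-of-maximum
prescription level and starve low-weight shots of prescription volume —
all-equal-weight multi-shot plans are usually poor starts.

**Greedy baseline** (`greedy_baseline`) is a deterministic, agent-free
reference. It packs shots by geometric set cover on the target's distance
transform — place a shot at the deepest unclaimed target voxel, claim a ball
around it — and then weight-refines. The collimator at each placement is the
largest whose 50% radius times a fit fraction γ fits the local depth,
capped by the collimator fitting the target's deepest point; each shot
claims `spacing_factor` times its 50% radius. A fixed 8-point rule grid
(γ ∈ {0.4, 0.55} × spacing ∈ {1.0, 1.1} × cap offset ∈ {0, −1}) is tried
and the best plan kept. Placement deliberately ignores dose: sequential
dose-guided placement is unstable under 50% renormalisation (each shot
raises the prescription level of its predecessors, so "fitting" choices
systematically under-cover), whereas cover-then-reweight is robust — the
deliberate near-surface overshoot (γ < 1) is trimmed by the weight pass.

## Synthetic phantoms (`gammaplan.phantoms`)

Phantoms emulate the size range and shape irregularity of intracranial
radiosurgery targets — spheres, volume-preserving ellipsoids (axis ratio
≤ 2), and connected unions of 3–6 spheres ("blobs") — on 1 mm grids, with an
optional shell-cap OAR at a chosen distance from the target surface. A
bisection on a global linear scale matches the voxelized volume to the
request within 1% (the spec of each phantom is a pure function of its seed).
They do **not** emulate anatomy: no image intensities, no realistic OAR
geometry, no skull boundary. Consequently, passing tests demonstrate the
mechanics and the optimisation behaviour of the planner under controlled
geometry, not clinical performance.

The packaged validation table (15 independent test cases; manual vs
automated coverage, selectivity and conformity) ships as a checksummed CSV
fixture used by the metric worked-example tests. Its printed column averages
are reproduced only where the printed average equals the recomputed average
of the printed rows at printed precision; the four columns whose printed
averages differ in the last digit from their own rows are not asserted.

## Problem sizes and determinism

The acceptance computation trains on a 0.9 cc sphere (1 mm grid, working
grid ≤ 40³) for 200 iterations at three seeds and reports mean best-plan
coverage and selectivity — sizes chosen so the whole computation is a
desk-scale, single-core run. Training typically finds a
criteria-satisfying plan within the first tens of episodes on this geometry.
Every random draw (network init, action sampling, batch shuffling) flows
from one integer seed through `numpy.random.Generator`; runs are
bit-reproducible on a given platform.

## Known limitations

* Targets above ~20 cc do not reach 90% coverage under the default 30-shot
  cap with an 18 mm largest aperture; clinical plans for such volumes use
  more shots or larger apertures.
* The dose model omits per-voxel depth, heterogeneity, and source-channel
  structure; the beam fixture is synthetic, so absolute index values are
  specific to it.
* Spill is measured on the cropped working grid; dose falling outside the
  crop (possible only for large collimators at the crop margin) is not
  counted against selectivity. The default 12 mm margin makes this
  negligible for shots placed inside the target.
* The in-episode action space fixes shot weight at 1.0; weights enter only
  through post-hoc refinement.
* `compare_cohorts` assumes approximately normal paired differences; with
  ~15 cases the t-test is adequate but the permutation oracle in the tests
  is the more defensible reference.
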