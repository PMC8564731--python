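# Methods

## Model

The model tracks 14 states. Receptors cycle between inactive (B),
active (B_act) and desensitized (B_de) conformations:

    dB/dt     = k1·B_de − kB·B·(EPI + kCL·CL)
    dB_act/dt = kB·B·(EPI + kCL·CL) − k2·B_act
    dB_de/dt  = k2·B_act − k1·B_de

Epinephrine (EPI) and CL 316243 (CL) act through the same activation
term; kCL rescales the weaker agonist. The receptor total is conserved
exactly.

Active receptors drive cAMP production (adenylyl-cyclase intermediates
are deliberately collapsed into the single constant k3). cAMP, free
Ca²⁺ and ATP exchange with the patch pipette by first-order diffusion
gated by the binary `pip` flag; flux into the pipette is scaled by
V_cell/V_pip (≈7·10⁻⁹, so the pipette acts as an effectively infinite
reservoir):

    dcAMP/dt    = kDiffcAMP·(pipcAMP − cAMP)·pip + k3·B_act − kdegcAMP·cAMP
    dpipcAMP/dt = −kDiffcAMP·(pipcAMP − cAMP)·pip·V_cell/V_pip

with analogous pairs for Ca²⁺ (removal kremCa) and ATP (degradation
kdegATP). Vesicles move from a constant reserve pool (Res) to the
releasable pool (Rel) under Ca²⁺/ATP control, fuse with the plasma
membrane pool (PM) when triggered by cAMP, and are exocytosed or
recycled:

    vRes_Rel = (Ca/(km+Ca))·(kCa2 + kATP2·ATP)·Res
    vRel_PM  = cAMP·(kcAMP + (Ca/(km+Ca))·ATP·kCaATP)·Rel
    dRel/dt  = vRes_Rel − vRel_PM + krel·PM
    dPM/dt   = vRel_PM − (krel + kexo)·PM
    dEndo/dt = kCacAMP·cAMP·Ca − kEndo·Endo
    dAdiponectin/dt = kexo·PM

The measured capacitance rate is ŷ = kscale·(kexo·PM − kEndo·Endo) in
fF/s. cAMP is strictly required for fusion, so a protocol without any
cAMP source produces no signal.

## Units and conventions

* Rate constants are **per second**. Experiment time grids, protocol
  durations and figure-style outputs are in **minutes**; the simulator
  converts once at its boundary. With the published optimal constants,
  per-second rates are the unique reading that reproduces the published
  response features simultaneously (exocytosis peaking near t = 2 min
  under stimulation, secretion essentially complete by 15 min of CL);
  per-minute rates put the peak beyond the 12-min recording window.
* cAMP and ATP are in mM, Ca²⁺/EPI/CL in µM, pool sizes in arbitrary
  units. The rate constants are non-identifiable, so unit choices only
  re-express constants; the published values are used verbatim.
* States measure the increase over basal levels, hence the resting cell
  is the zero state apart from receptors and pools.

## Initial conditions (calibrated scales)

The initial condition places all receptors in the inactive state and
all mediators at basal: B(0) = B_total·(1 − knockdown), everything else
zero except the pools and the pipette loading. Three scale constants
are not published and were calibrated once against printed, figure-level
behaviour, then frozen:

* **B_total = 100 a.u.** Receptor amount sets how fast the releasable
  pool empties relative to the recording; it was chosen so that
  simulated CL-stimulated secretion is essentially complete by 15 min
  (fold over 15-min secretion at 30 min within the published 1.0–1.15
  range) with the exocytosis peak near 2 min. Much smaller totals put
  the model in its linear regime (knockdown would inhibit exactly
  proportionally, and the peak would drift past 12 min); much larger
  totals make depletion instantaneous.
* **Rel(0) = 1000 a.u.** The endocytosis flux kEndo·Endo is independent
  of pool sizes while exocytosis scales with them, so the pool scale
  fixes their ratio; 1000 keeps the Ca²⁺-containing condition's net
  rate positive at its peak, as observed.
* **Res = 4000 a.u.** The reserve pool exceeds the releasable pool, so
  Ca²⁺-dependent replenishment visibly sustains Rel over 30 min
  (≈10 % residual with 1.5 µM Ca²⁺ versus ≈1 % without).

The knockdown inhibitions and all fold quantities are ratios in which
kscale cancels; they emerge from these scales rather than being fitted.
The default kscale = 4.0 fF/s per model rate unit places simulated CL
peak rates near 16 fF/s (the published recordings span ≈13–20 fF/s) and
matters only to the synthetic-data generator.

## Numerics

LSODA (via `scipy.integrate.odeint`) with an analytic Jacobian; both
the right-hand side and the Jacobian are numba-compiled. The ATP
degradation rate (≈2·10³ s⁻¹) makes the system stiff. Reporting
tolerances are rtol 10⁻⁸ / atol 10⁻¹⁰; fitting uses 10⁻⁶ / 10⁻⁸.
States are clipped to zero when the solver leaves them within −10⁻⁹;
larger negativity, non-finite output or receptor-conservation drift
beyond 10⁻⁶ relative raise a simulation failure, which the estimation
layer maps to infinite cost. Peak locations are read from a 0.01-min
grid with quadratic refinement of the argmax triple.

## Estimation

kscale has a closed-form weighted least-squares solution and is
profiled out inside every cost evaluation; consequently the χ² test
runs at N−1 degrees of freedom for N data points, and the search space
is the 22 rate/volume parameters in log₁₀ over the published bounds
(10⁻⁴–10⁴ for rates; 2–6·10⁻⁵ l and 8.6–171.7·10⁻¹⁵ l for the
volumes).

The search is a seeded multi-stage procedure:

1. **Screen.** A scrambled Sobol sample (default 4096 points) is
   scored by cost, and each candidate is additionally checked against
   the peak-timing constraint — the exocytosis peak of every
   extracellularly stimulated condition must fall inside a configurable
   window (default 1–4 min). This prior-knowledge constraint is
   essential: the observation grids are too sparse to see a transient
   spike before the first post-zero time point, and unconstrained
   refinement reliably converges to such spurious early-spike optima.
2. **Refine.** Local refinement uses bounded trust-region least
   squares (`least_squares`, TRF, `x_scale='jac'`) and runs along two
   complementary routes, 20 starts in total: the best *peak-feasible*
   candidates are refined directly on the weighted residual vector
   augmented with a hinge barrier, while the best *unconstrained*
   candidates are refined on the plain residuals first and then
   repaired by a barrier refinement. The barrier demands, on a 0.1-min
   grid, that the response outside the peak window stay below 97 % of
   the in-window maximum; the 3 % clearance keeps the barrier inactive
   for well-shaped solutions (the generating model's outside/inside
   ratio is ≤0.94) while preventing the optimizer from parking the peak
   on the window edge. Each start gets two perturbation restarts
   (σ cycling 0.2/0.5 in log₁₀).
3. **Intensify.** The incumbent receives six further iterated-local-
   search restarts with a σ ladder (0.1/0.3/0.6).

Refined sets are re-checked against the hard peak window (violators are
rejected outright, never penalized into the result), and every
evaluated set below the χ² threshold that satisfies bounds and
constraint enters the archive (deduplicated, best 200) for uncertainty
profiling. The whole pipeline is deterministic given the seed. These
budgets are desk-scale design choices; they recover synthetic data
generated at the study conditions in a few minutes on one core.

## Prediction uncertainty

For a quantity q(θ) at one protocol and time, the band edge solves
min/max q(θ) s.t. cost(θ) ≤ cost(θ*) + χ²(0.05, 1), relaxed to the
penalized objective ±q(θ) + penalty with
penalty = |q(θ)| + cost(θ) − limit when the cost exceeds the limit and
0 otherwise; maximization is the negated minimization. The optimizer
(Nelder–Mead in log space, default 5 restarts seeded from the archive's
best members plus jittered copies) tracks the best *hard-feasible*
value seen at any evaluation, so every reported bound is achieved by a
parameter set whose recomputed cost truly respects the limit — the
penalty value itself is never reported. ŷ-type targets rescale each
candidate by its own profiled kscale. No multiplicity correction is
applied across profiled points (each point is an independent 1-df
subproblem), and bands are reported only at the profiled times.

## Synthetic data

The generator emulates the statistical interface of the recordings:
for each condition it simulates the noise-free trace at the observation
grid (default 0–12 min in 2-min steps, the four built-in conditions),
draws n ∈ [4, 15] Gaussian replicates per point with
sd = 0.25·max|ŷ| over the trace, and records the sample mean with the
known SEM = sd/√n. Because the SEM is the true standard error rather
than a sample estimate, each standardized residual of the generating
model is exactly standard normal and E[cost(θ_true)] equals the number
of data points — the calibration the χ² test assumes. The generator
does not emulate between-cell heterogeneity, seal artifacts, rundown,
or correlated noise along a recording; passing recovery therefore
demonstrates that the pipeline is self-consistent under its own error
model, not that real recordings satisfy that model.

The recovery harness regenerates data from the published parameters,
refits from scratch, and scores (i) the χ² verdict, (ii) the fraction
of observation points where the refit prediction lies within 3 SEM of
the noise-free truth (parameters themselves are non-identifiable, so
recovery is judged on predictions), and (iii) optionally the coverage
of the truth by prediction bands.

## Known limitations

* The three initial-condition scales are calibrated to printed
  figure-level quantities, not fitted to data; other (B_total, pools)
  combinations reproducing the same printed behaviour exist.
* The desk-scale optimizer can return best costs near the χ² threshold
  on unlucky noise draws; the published cluster-scale campaign is out
  of scope by design.
* Ca²⁺ buffering, adenylyl-cyclase intermediates, Epac1/VAMP
  mechanisms and autocrine feedback are not modelled.
* Pipette attachment and extracellular stimulus both switch on at t = 0
  and persist; no pre-stimulus equilibration is simulated.
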