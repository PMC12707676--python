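# Methods

## Untreated model

Cells are typed by cell-cycle phase and generation. Phase completion times
are independent gamma variables ψᵢ with shapes α₁, α₂, α₃ (G1, S, G2/M) and
a common rate β₀ (1/h); sharing β₀ ties the mean cycle length to Σαᵢ/β₀ and
its variance to Σαᵢ/β₀², and makes the characteristic equation of the
supercritical process solvable in closed form. Mitosis produces exactly two
daughters; there is no spontaneous untreated death, no explicit G0 state,
and no crowding — assumptions appropriate for exponentially growing in
vitro monolayers, which is the regime the framework targets.

Expected counts are computed from the renewal representation

    M(t) = Σ_k (G m)^{*k}(t) ∗ [I − G(t)],

with **G** the diagonal matrix of state-duration CDFs and **m** the expected
offspring matrix. Because the generation-expanded state graph is acyclic,
convolution powers beyond the longest directed path vanish and the
truncated sum is exact, not an approximation. The generation horizon
`n_gen` is chosen per run so that essentially no mass reaches the last
generation inside the simulated window (rule of thumb:
`ceil(horizon/mean_cycle) + 3`).

### Balanced growth

The Malthusian rate is γ = β₀(2^{1/Σα} − 1), verified against a bracketing
root of 2·ψ̂₁ψ̂₂ψ̂₃(γ) = 1 to 1e−10. The stable phase fractions are
pᵢ = 2[ψ̂₁···ψ̂ᵢ₋₁(γ) − ψ̂₁···ψ̂ᵢ(γ)]; they sum to one exactly by the
characteristic equation. Balanced growth is detected on a simulated
trajectory (T_SSD) as the first time from which the squared difference
between the G1 fraction and its value five hours earlier stays below a
tolerance (default 1e−4). The persistence requirement matters: starting
from 100% G1 the fractions ring for several cycles, and the lagged
difference crosses zero at every oscillation crest; a pointwise test would
fire there while the fractions are still ~0.13 from equilibrium. With the
default tolerance, T_SSD for the NSCLC baseline is ≈100 h with fractions
within 0.006 of the closed form. The printed-threshold reading "10e−4" is
ambiguous (1e−3 vs 1e−4); 1e−4 is the default and the knob is exposed.

## Treatment state machines

Drug exposure is continuous from T_SSD (no pharmacokinetics). The cycling
population at T_SSD seeds the treated graph through "occupant" states whose
durations are residual times: for a cell observed mid-phase in a population
growing at rate γ, the age density within the phase is ∝ e^{−γa}(1 − G(a)),
giving the residual CDF

    R(t) = ∫ e^{−γa}[G(a+t) − G(a)] da / ∫ e^{−γa}[1 − G(a)] da,

computed by quadrature (γ = 0 recovers the classical equilibrium
residual-life law; an exponential phase is memoryless, which the tests
check). Cells born after treatment start fresh phases.

Drug effects are modeled as *extensions* of the cycle: each biological
phase keeps its (residual or full) baseline duration, and drug-induced
repair/arrest states append Weibull-distributed downtime at the phase
border. Arrest states inherited by daughters (G1arrest, Sarrest, G2Marrest)
follow the downtime-then-progression construction: their residence time is
the Weibull downtime convolved with the baseline phase duration, with a
competing death edge whose waiting time has its own Weibull law (D_d). The
border states (UR/FR/MS after G2/M, UR/FR after S, the G1/S block) are pure
downtimes during which the cell remains in its phase; death there resolves
at the end of the downtime. Cells in a death-transit state still count as
live in their phase; apoptotic cells occupy a shared compartment for a
fixed 5 h (configurable) and are then removed. Phase fractions are always
normalized over live, non-apoptotic states (flow cytometry gates live
cells); apoptotic and cumulative-dead counts are reported separately, along
with a "committed dead" curve (cells that have drawn a death fate but may
still be in transit) that separates lethality from apoptosis timing.

Fate wiring, per drug:

* G2/M drug — a cell completing G2/M branches into unfaithful repair
  (q₁, divides into two damaged daughters), faithful repair (q₂, divides
  into two clean daughters), pre-slippage arrest (q₃, survivor slips out of
  mitosis as a single damaged cell), or an unperturbed division. Damaged
  daughters traverse G1arrest; survivors either shed the damage and re-enter
  a normal S phase (probability q₄ of the original fate mass) or carry it
  through Sarrest into the next — again drug-exposed — G2/M. Cells that
  were in G1 at treatment traverse a recalibrated first S phase (Weibull
  downtime with shape b_S and scale a_S, convolved onto ψ₂).
* S drug — a cell completing G1 is blocked at the G1/S border with
  probability q₁ (Weibull block duration, death at its end with m_d); a
  cell completing S branches into UR (q₂) or FR (q₃) downtimes; unresolved
  UR damage arrests the next G2/M (G2Marrest: divide or die). Undamaged
  generation-1 lineages traverse a recalibrated first G2/M.
* Combination — G1/S passages obey the S-drug rules and G2/M passages the
  G2/M-drug rules, each scaled by its own dose; the apoptotic compartment
  is shared. Damaged-lineage passages (G1arrest/Sarrest) follow the
  damage pathway and skip the G1/S border block; these states only receive
  mass when the G2/M drug is present, so each single-drug model is an exact
  special case of the combination graph.

### Dose scaling

Two Hill effects per drug share one coefficient n (fixed at 1 by default,
config-exposed): E(D) scales every downtime scale λ = λ_max·E *and* the
drug-hit branch probabilities q = q_max·E, while E_d(D) scales every death
probability m_d = m_d_max·E_d. Scaling the q's is a deliberate design
choice: the branch into a repair/arrest state is itself a consequence of
drug-induced damage, so its frequency must vanish with the dose. It also
makes dose 0 an *exact* reduction — all downtimes become instantaneous
(Weibull scale 0 is a legal degenerate state), no deaths occur, no branch
is taken, and the treated expected counts coincide with the untreated ones
to round-off. The Table-value q's are therefore maxima approached at
saturating dose. The first-cycle recalibration scales (a_S, a_G2M) are
treated the same way for the same reason. EC50s are fixed inputs taken from
viability/growth-inhibition assays; they are not calibrated here.

## Numerics

Durations are discretized on a uniform grid (default step 0.1 h) as exact
CDF differences on half-offset bins, K[k] = G(t_k + h/2) − G(t_k − h/2),
which conserves mass exactly and assigns each transition a zero-mean timing
error. Survivals are taken as the complement of the kernel cumulative
(1 − ΣK), making occupancy + departures exactly conservative bin by bin;
the resulting curves are observations at t_k + h/2 and are recentered onto
the grid by neighbor averaging. The combination is second-order accurate:
halving the step changes 72 h phase fractions by ~3e−5, and expected counts
agree with the exact-time stochastic simulator within Monte-Carlo error at
10,000 lineages. (Evaluating survivals exactly at grid points instead
double-counts cells in transit within half a bin — a first-order error of
about 1% per 60 h that the Monte-Carlo cross-check exposes.) Convolutions
use zero-padded FFTs with entry masses truncated to the grid after every
Neumann step, which prevents circular wrap-around of long-downtime mass.

The stochastic oracle is event-driven (heap ordered by exit time, ties by
cell id): durations are drawn exactly (inverse transform for residual
laws, sums of draws for convolutions), fates at state entry, binning only
at output. Reproducible bit-for-bit under a fixed seed.

## Calibration

The likelihood treats observed per-phase fractions as model predictions
plus independent zero-mean Gaussian noise with per-phase variances σ²_p;
for untreated fits the residual vector concatenates the simulated
trajectory and the analytic balanced-growth fractions (1:1 weight,
config-exposed), which anchors the long-run behavior. Priors are uniform
boxes — defaults: shapes (2, 25), rate (0.3, 5), variances (1e−6, 0.05),
treatment probabilities (0, 1), scales (0.2×, 3×) — deliberately generous
and not claimed to match any published choice. The σ² are sampled jointly
with the model parameters. RAM uses target acceptance 0.234 and step size
η_n = min(1, d·n^{−2/3}); burn-in defaults to 50%, no thinning; 50%
credible intervals are the default reporting convention. Treated-model
fits estimate a chosen subset of drug parameters with everything else
fixed, reflecting the weak identifiability of the full 20+-parameter
block.

## Sensitivity analysis

First- and total-order Sobol indices are estimated with the Saltelli
scheme on low-discrepancy samples (base size a power of two). Outputs are
phase fractions at selected post-treatment times (default 12, 24, 48,
72 h), one decomposition per output, no scalarization. The reduced
treated-model analysis (5 parameters, N = 2¹⁰, late G2/M fraction) ranks
the unfaithful-repair downtime scale first and the fate probabilities above
the death-transit timing scale, consistent with the scientific expectation
that repair-duration and fate-split parameters dominate late-time phase
distributions.

## Synthetic data

The generator emulates flow-cytometry phase-fraction trajectories: engine
fractions at the sampling times plus independent Gaussian noise per phase
(default σ² = 8e−4 per phase, i.e. ±2.8 percentage points — the scale of
treated-series measurement noise in the reference calibrations), clipped
to [0, 1] only on extreme draws (logged). Noise is *not* renormalized
across phases, matching the independence assumption of the likelihood.
What it does not emulate: correlated gating errors, drifting instrument
response, cell-count (multinomial) noise that shrinks with sample size, or
raw FCS events. Passing recovery tests therefore demonstrate correctness
of the inference machinery under the model's own noise assumptions, not
robustness to real cytometry artifacts.

## Default problem sizes

Simulations use step 0.1 h and horizons of 60–72 h post-treatment with 6–8
generations; calibration predictors use step 0.2–0.25 h (fraction error
≪ measurement noise); the oracle comparison uses 10,000 ancestors; RAM
runs 20,000–50,000 iterations; Sobol oracles use N = 2¹³ and the treated
analysis N = 2¹⁰. These sizes make every headline quantity reproducible in
minutes on a single core.

## Known limitations

* Dose–response is phenomenological (shared Hill curves); no mechanistic
  drug interaction (Bliss/Loewe) and no pharmacokinetics.
* Absolute dead-cell counts over a fixed window need not increase with
  dose: strong cytostatic arrest (e.g. the ~75 h G1/S block at saturating
  S-drug dose) defers death beyond the window and suppresses the at-risk
  population. Live-cell suppression is monotone in dose; interpret
  lethality over fixed windows with the committed-dead curve alongside
  the apoptotic counts.
* Damage inheritance is binary (arrested vs clean daughters); repair
  kinetics do not depend on accumulated damage load.
* Second moments (count variances) are not computed; the agent simulator
  is the route to distributional quantities.
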