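# branchcycle

Multi-type Bellman–Harris branching-process modeling of cancer cell-cycle
dynamics under phase-specific chemotherapy.

`branchcycle` is for quantitative cancer biologists and modelers who want to
turn flow-cytometry phase-fraction time series (percent of live cells in G1,
S and G2/M over time) into mechanistic statements about how a drug perturbs
the cell cycle: how often drug-hit cells enter faithful vs unfaithful DNA
repair, arrest, or slip out of mitosis; how long those states last; how
lethal they are; and how all of this scales with dose.

## The model

Untreated cells traverse G1 → S → G2/M and divide into two G1 daughters.
Phase completion times are gamma distributed with phase-specific shapes
α₁, α₂, α₃ and a common rate β₀,

    ψᵢ(τ) = β₀^αᵢ τ^(αᵢ−1) e^(−β₀ τ) / Γ(αᵢ),

so the population is a multi-type age-dependent (Bellman–Harris) branching
process. Expected counts per state follow from the renewal equation: with
duration CDFs stacked in a diagonal matrix **G**(t) and the expected-offspring
(transition) matrix **m**, the generation-expanded moment matrix is the
truncated Neumann series of convolution powers

    M(t) = Σₖ (G m)^{*k}(t) ∗ [I − G(t)],

which the engine evaluates exactly (the truncation matches the graph's
longest path) by FFT convolution on a uniform grid (default step 0.1 h).

The population converges to asynchronous balanced growth with Malthusian
rate γ solving 2·ψ̂₁(γ)ψ̂₂(γ)ψ̂₃(γ) = 1, in closed form

    γ = β₀ (2^{1/(α₁+α₂+α₃)} − 1),

and asymptotic phase fractions pᵢ = 2[ψ̂₁···ψ̂ᵢ₋₁(γ) − ψ̂₁···ψ̂ᵢ(γ)].
That balanced state is the initial condition for treatment runs (detected as
T_SSD, the time from which the G1 fraction stops drifting).

Treatment enlarges the state machine. G2/M-phase drugs (docetaxel,
paclitaxel) send a cell finishing mitosis into unfaithful repair (UR, prob
q₁), faithful repair (FR, q₂) or pre-slippage arrest (MS, q₃); UR/FR
survivors divide, an MS survivor slips out of mitosis without dividing, and
daughters of UR/MS mothers inherit damage (arrested G1/S passages with their
own death clocks). S-phase drugs (gemcitabine) block the G1/S border and
send S-phase cells into UR/FR states whose unresolved damage arrests the
next G2/M. State residence times are Weibull "downtimes" convolved with the
baseline phase durations; downtime scales λ, death probabilities m_d and the
branch probabilities q are scaled by saturating Hill effects of dose, so
dose 0 reduces exactly to the untreated process. An agent-level stochastic
simulator of the same state graphs serves as an independent oracle for the
expected-count engine.

Calibration treats observed fractions as model output plus independent
Gaussian noise per phase and samples the joint posterior of model parameters
and noise variances with the Robust Adaptive Metropolis (RAM) algorithm;
variance-based (Sobol) sensitivity analysis ranks the treatment parameters.

## Worked example

Fit the untreated model to a synthetic flow-cytometry trajectory generated
at the reference gastric-cancer calibration (α = 10.156, 11.068, 10.147,
β₀ = 1.797):

```python
from branchcycle import PhaseFractionModel, MODEL1_BASELINE
from branchcycle.synthetic_data import SyntheticSpec, generate_trajectory

data = generate_trajectory(SyntheticSpec(MODEL1_BASELINE, seed=2024))
model = PhaseFractionModel(data, kind="untreated", step=0.2)
result = model.fit(n_iter=20_000, seed=7)
print(result.summary())
```

```
Phase-fraction branching-process model
  kind: untreated    draws: 20000 (burn-in 50%)
  acceptance rate: 0.232   target: 0.234

                mean  ci50_low  ci50_high
alpha1         10.26     9.936      10.57
alpha2         11.18     10.83      11.54
alpha3          10.6     10.28      10.91
beta0          1.837      1.78      1.889
sigma2_g1   0.001318 0.0009326    0.00159
sigma2_s    0.001273 0.0008504   0.001524
sigma2_g2m 0.0007324 0.0004971  0.0008803
```

The posterior means sit close to the generating values (the gamma shapes
are correlated with β₀, so individual shapes carry wider uncertainty than
the mean cycle length Σα/β₀); the recovery check in the test suite requires
at least three of the four generating parameters inside their 95% credible
intervals. From the fitted baseline,

```python
from branchcycle import growth_rate, asymptotic_fractions, MODEL2_BASELINE
print(growth_rate(MODEL2_BASELINE))        # 0.04542 per hour
print(asymptotic_fractions(MODEL2_BASELINE))
# (0.4056, 0.3149, 0.2794)  = balanced-growth G1/S/G2M fractions
```

i.e. the NSCLC reference line doubles every ln 2/γ ≈ 15.3 h with ~41% of
live cells in G1 at steady state. A treatment run then starts from that
state:

```python
from branchcycle import simulate_treatment_run, MODEL2_G2M
from branchcycle.distributions import TimeGrid

curves, t_ssd = simulate_treatment_run(
    MODEL2_BASELINE, g2m=MODEL2_G2M, dose_g2m=120.0, grid=TimeGrid(0.1, 72.0))
print(round(t_ssd, 1), round(curves.fractions["G2M"][240], 3))
# 100.4 0.562  -> mitotic arrest swells the G2/M fraction (peak 0.66 near
#                 12 h) before death and recovery reshape the distribution
```

The same models are scriptable from the shell:

```sh
branchcycle steady-state --preset model2
branchcycle dose-scan --preset model3 --out runs/gem
branchcycle sensitivity --preset model2 --n 1024 --out runs/gsa
```

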