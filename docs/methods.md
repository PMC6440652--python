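# Methods

`hsoed` implements deterministic ODE models of two doxorubicin (DOX)-inducible
synthetic reporter circuits together with the machinery needed to design
informative identification experiments for them: forward sensitivity analysis,
Fisher-information design criteria with Crámer–Rao lower bounds (CRLBs), a
harmony-search (HS) metaheuristic with GA and PSO baselines, and a two-stage
nested search that selects the input level and the sample size.

## Circuit models

Both circuits are modelled as mass-action / Hill ODE systems in units of
minutes and micromolar, driven by a scalar DOX input u(t).

**Unbuffered circuit** (3 states): DOX activates production of the
transcription factor SKN7m (X_m) through a Hill term
k_m·u^n1/(K_dox + u^n1); SKN7m binds the synthetic promoter P_TR-SSRE
(total pool p_T) to form the complex C_m with rates k_on/k_off; free SKN7m
activates GFP (G) through a second Hill term. All species degrade linearly.

**Buffered circuit** (10 states, 23 kinetic parameters): DOX drives a
STAT5-HKRR fusion Z that autophosphorylates (k_p, k_p′) and relays its
phosphate through YPD1 (W) to SKN7 (X) via the phosphotransfer rates
k1…k4, with k1 ≥ k3 and k2 ≥ k4 and all four confined to [1, 50] μM⁻¹
(enforced at model construction). Doubly phosphorylated SKN7 (X**) activates
GFP and binds load sites (C*, C**). The retroactivity terms r1, r2 are
constant source terms on the phosphorylated SKN7 pools: whether they are
constants or load-dependent functions is an open modelling question, and the
constant reading is the simplest consistent one.

The kinetic/fixed split is chosen so the printed parameter counts come out
exactly: the Hill coefficients (n1, n2) and half-saturation constants
(K_dox, K_gfp) are fixed in both circuits; the promoter-site total p_T is
additionally fixed in the buffered circuit (9 + 14 other rates = 23) but
belongs to the 9-parameter kinetic vector of the unbuffered circuit
(13 symbols − 4 fixed = 9). Genetic load conditions (model+0x/+1x/+2x) are
realized as a `load_factor` ∈ {1, 2, 3} multiplying p_T.

### Default parameter values

No benchmark parameter set exists for these circuits in the literature this
package draws on, so the shipped defaults are **repository values**, chosen
once for (a) realistic response timescales — degradation/dilution rates of
order 0.01 min⁻¹, i.e. protein half-lives near 70 min, give reporter rise
times of a few hundred minutes within the 3000-min experiment window — and
(b) practical identifiability of the binding pair: with fast binding
(k_off ≫ other rates) the promoter complex is in quasi-equilibrium and GFP
data constrain only the ratio k_on/k_off; the defaults
k_on = 0.02 μM⁻¹min⁻¹, k_off = 0.01 min⁻¹ put the binding relaxation on the
same timescale as the rest of the dynamics, so the pair is separately
identifiable (sensitivity-column correlation ≈ −0.95, safely away from ±1).
Every default can be overridden per parameter.

A structural caveat the sensitivity analysis makes visible: in the
unbuffered model k_off and δ_c enter the dynamics only through the sum
k_off + δ_c (complex decay returns SKN7m either way), so that pair is
exactly non-identifiable from GFP data; estimation therefore frees k_on and
k_off while holding δ_c fixed.

### Initial conditions and simulation

All states start at zero except the buffered total pools
W_T(0) = k_w/δ_W and X_T(0) = k_x/δ_X (their unforced steady states), which
avoids a production transient unrelated to the input. Integration uses
LSODA with rtol = 1e-8, atol = 1e-10 by default, split piecewise at the
input's discontinuities so step and square-wave edges are resolved exactly.
Square waves have 50% duty cycle with the high phase first. Output values in
[−1e-7, 0) are integrator round-off and are clipped to zero; anything more
negative is left visible.

## Sensitivity analysis

Forward sensitivities S(t) = ∂x(t)/∂p solve dS/dt = J_x S + J_p with
S(0) = 0, integrated as one augmented system. The Jacobians are derived
symbolically (sympy) from a mirror of the hand-coded right-hand sides and
compiled once per circuit; the Hill exponents are substituted numerically
before differentiation because the symbolic derivative of x^n carries a
spurious 1/x that is singular at x = 0.

The initial state is treated as a **fixed experimental condition**: S(0) ≡ 0
even though the buffered pool initial values are computed from the reference
parameters. The finite-difference fallback (central differences, relative
step 1e-5 with absolute floor 1e-8) therefore holds the initial state at its
reference value while perturbing parameters, and the two routes agree to
better than 1e-3 relative per parameter column when both run at tight solver
tolerance (rtol = 1e-12); at that accuracy the finite-difference quotient for
small-magnitude parameters is no longer dominated by solver noise.

At steady state the unbuffered GFP level is independent of k_on/k_off
(total production balances degradation), so their sensitivities are
transient: negative for k_on (sequestration of free SKN7m slows the
reporter) and positive for k_off during the reporter **rise phase**, which
this package defines as [0, 300] min under the default step input (the
reporter reaches 90% of steady state near 490 min and the sensitivity signs
cross near 470 min). Documentation and tests of the sign pattern refer to
this window.

## Fisher information, criteria, CRLBs

With independent Gaussian measurement noise of known per-time standard
deviation σ_i on the observed state (GFP fluorescence only, by default),
F = Σ_i S(t_i)ᵀ diag(1/σ_i²) S(t_i). Criteria: A = tr(F⁻¹), D = det F,
E = λ_min, modE = λ_max/λ_min (the condition number; 1 = perfectly balanced
information). CRLBs are the diagonal of F⁻¹ (variances; a square-root view
is provided). F is treated as singular when λ_min/λ_max < 1e-12, in which
case modE and A are reported infinite and parameters with weight in the
null space get infinite bounds — the numerically robust flagging of
practical non-identifiability.

## Fit objectives and goodness of fit

RMSE and the σ-weighted residual sum wRSSE = Σ((y−ŷ)/σ)² are the error
indexes; under the true model with known σ, wRSSE ~ χ² with
r = n_data − n_params degrees of freedom, giving the GOF p-value, and normal
QQ plots use plotting positions (i − 0.5)/n. The sample-size objective is

J(n_m) = Σ(y_i − ŷ_i)² + λ·(n_m − n_p)/n_m,

with λ = 0.8 by default and the penalty reported separately. The accuracy
term is the raw residual sum as printed; a σ-weighted variant is available
behind a flag because the surrounding prose and the printed formula point in
different directions. Note a consequence of the raw form: each additional
noisy measurement adds about σ² to the first term, so with well-identified
parameters the sweep favors the smallest admissible n_m; the sweep exists to
make that trade-off explicit rather than to guarantee an interior optimum.

## Optimizers

`hs_minimize` is standard harmony search: memory of HMS vectors; per
dimension, with probability HMCR copy a memory value and with probability
PAR pitch-adjust it within the bandwidth, otherwise draw uniformly from the
box; a new vector replaces the worst row only on strict improvement, making
the incumbent trace monotone. Defaults HMS = 15, PAR = 0.2,
bandwidth = 0.05·(ub − lb); HMCR presets 0.2 (coarse screening context) and
0.8 (nested-OED context) are both provided. Dimensions may be restricted to
discrete grids (random draws and pitch moves then live on the grid), which
makes HS directly comparable with exhaustive screening.

For the inner estimation problem the package uses an annealed variant
(PAR = 0.9, HMS = 10, bandwidth decaying geometrically from 0.2 to 5e-5 of
the box width over the run): the wRSSE landscape in (k_on, k_off) is a
narrow correlated valley, and a static 5%-bandwidth pitch cannot both
traverse it and resolve its bottom within a 2000-evaluation budget, while
the wide-to-fine schedule recovers the generating values to well under 5%
across seeds. Estimation bounds default to a 5× prior box around nominal
values, mirroring a two-stage initial-estimation-then-refinement protocol.

Baselines use the comparison settings: real-coded GA (population 50,
tournament selection, arithmetic crossover, Gaussian mutation, elitism 1)
with rates 0.8/0.2 assigned as printed to mutation/crossover — conventional
usage usually reverses these labels, so both are plain config knobs — and
global-best PSO with inertia weight 1, c1 = c2 = 1, velocity clamped to half
the box width. All optimizers are bit-reproducible given a seed.

## Nested OED

The outer loop minimizes cfun1(u) = modE of the FIM at the best available
estimate (a combined modE + wRSSE variant is a flag); the inner loop
minimizes cfun2 = wRSSE. Each outer iteration re-initializes a small harmony
memory of input levels with the incumbent u* in row 1, evaluates every
candidate, and keeps the incumbent only on strict improvement (earliest
candidate wins ties). Measurements for a candidate u are generated with a
seed derived deterministically from (master seed, u), so cfun1 is a
deterministic function of u — otherwise memory comparisons would be
noise-dominated — and evaluations are memoized per u. Data generation always
runs at full solver accuracy; only candidate fits inside the search relax to
rtol = 1e-6. The feasible band is [1, 30] μM, the default duration
t_f = 3000 min, with n_m = 50 evenly spaced sampling times (the sampling
rule is otherwise unspecified, and evenly spaced is the neutral choice).

## Synthetic measurements

`generate_measurements` samples the GFP trajectory at n_m evenly spaced
times and adds independent Gaussian noise with
σ_i = max(sigma_rel·|y_i|, sigma_floor); the defaults (5% relative, 1e-3 μM
floor) are repository choices. The recorded σ_i are the single source of
truth reused for wRSSE weighting and FIM construction. Negative noisy values
are kept so the Gaussian error model holds exactly for GOF calibration
(clipping is available for realism, at the cost of that exactness). The
generator emulates fluorescence time series from a deterministic circuit
with known heteroscedastic Gaussian noise; it does not emulate cell-to-cell
variability, autofluorescence background drift, temporal correlation of
instrument noise, or sampling jitter — so passing tests certify the
estimation and design machinery under the stated error model, not robustness
to those real-data effects.

## Numerical choices, in one place

- ODE solver LSODA; simulation rtol 1e-8/atol 1e-10; fitting 1e-6/1e-9;
  oracle comparisons 1e-12/1e-13.
- Negative-state clip threshold 1e-7 (round-off only).
- FIM singularity threshold λ_min/λ_max < 1e-12.
- Finite differences: central, relative step 1e-5, absolute floor 1e-8.
- Tie-breaks everywhere: earliest / lowest index.
- Seeds: every stochastic component takes an explicit seed; nested seeds are
  derived via a 4-byte blake2b hash, keeping them below 2³¹.

## Known limitations

- The two circuit topologies are fixed; no structure inference, and no
  stochastic (SSA/SDE) simulation — the framework is deterministic.
- Only the scalar input level is optimized; waveform shape and period are
  fixed design choices, as is the evenly spaced sampling rule.
- Local (derivative-based) identifiability only; no global sensitivity or
  Bayesian design criteria.
- CRLB values depend entirely on the chosen parameter values and noise
  levels; with repository defaults they support qualitative ordering
  (which designs are better) rather than quantitative comparison with any
  external experiment.
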