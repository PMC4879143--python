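# Methods

## Model

A stimulus is a square-wave pulse train with NoP pulses, interpulse
interval IPI (ms), pulse width PW (ms) and amplitude A (mA). Detection is
modeled as a first-spike ("hazard") process in four stages.

**Peripheral activation.** The afferent membrane (time constant τ₁)
filters the brief pulse, giving the effective amplitude
fA = A·(1 − e^(−PW/τ₁)); fibers are recruited through the
threshold-linear stage [fA − α₁]₊ = π(fA − α₁)H(fA − α₁), with α₁ the
lumped afferent activation threshold. The factor π comes from the
geometric derivation of the underlying biophysical model (integration of
recruitment over the skin area around the electrode) and is kept exactly.
The model contains no axonal propagation, T-junction filtering or
short-term synaptic plasticity; a pulse evokes at most one afferent
volley.

**Postsynaptic current and potential.** Each pulse at time t_k injects an
exponential current kernel (D/τ_s)·e^(−(t−t_k)/τ_s), D = [fA − α₁]₊. The
secondary-neuron PSP obeys the leaky integrator τ₂ẋ = −x + I(t),
x(0) = 0, solved in closed form by superposition:
per-pulse contribution D/(τ₂ − τ_s)·(e^(−Δ/τ₂) − e^(−Δ/τ_s)). The
degenerate case τ₂ = τ_s (never reached at physiological values) uses the
limiting form D·Δ/τ₂²·e^(−Δ/τ₂) rather than an epsilon perturbation. The
closed form is the production path; a stiff ODE integration exists only
as a test oracle.

**Hazard and psychometric function.** Spiking is a non-homogeneous
Poisson process with rate λ(x) = λ_L/(1 + exp((α_L − x)/σ_L)); detection
is at-least-one-spike in the trial window, Ψ = 1 − exp(−λ_T) with
λ_T = ∫₀ᵀ λ(x(t)) dt. When the sigmoid argument exceeds 700 the rate is
returned as exactly 0 to avoid overflow during extreme parameter sweeps.

**Units.** mA and ms everywhere. mA/ms is numerically equal to A/s and
events/ms to kHz, so central parameters quoted in A/s or kHz are used
verbatim with no conversion constants.

### Parameters

| name | meaning | unit | reference |
|------|---------|------|-----------|
| α₁ | afferent activation threshold | mA | 0.125 |
| τ₁ | afferent membrane time constant | ms | 0.2 |
| τ₂ | secondary-neuron time constant | ms | 45 |
| α_L | central activation threshold | mA/ms (≡ A/s) | 0.00417 |
| σ_L | central slope parameter | mA/ms | 8.33×10⁻⁵ |
| λ_L | maximal population firing rate | events/ms (≡ kHz) | 0.01 |
| τ_s | synaptic kernel time constant | ms | 1.5 |

σ_L ≪ α_L (ratio ≈ 50), so the rate function is nearly a step at rest and
baseline hazard is negligible (Ψ(0) < 10⁻¹⁰).

## Numerical choices

**Trial window.** λ_T nominally runs over a trial interval of duration T;
the window is set to the last pulse time + 15·τ₂, where the PSP has
decayed by e^(−15) and — because the sigmoid suppresses the rate
doubly-exponentially below threshold — the remaining tail contributes
less than any tolerance in use. Experimental inter-stimulus spacing (~3 s)
always exceeds this window. λ_T is verified invariant (within the
quadrature tolerance) under doubling of the window.

**Quadrature.** Fixed-step composite Simpson with step
min(τ_s/5, τ₂/200), split at every pulse onset (the integrand has a kink
there, and is smooth in between). Target absolute error `quad_tol` is
10⁻⁹ by default.

**Threshold solve.** Ψ is monotone nondecreasing in A, so Ψ(A) = 0.5 has
a unique root whenever Ψ(0) < 0.5. The upper bracket starts just above
the peripheral turn-on amplitude α₁/(1 − e^(−PW/τ₁)) and doubles until
Ψ > 0.5 (erroring out at `amplitude_bracket_max`); Brent's method then
refines the root. `root_tol` (10⁻⁶ mA) is the guaranteed accuracy of
A₅₀; internally the solver runs to a tighter bracket so that the closure
|Ψ(A₅₀) − 0.5| ≤ 10·`quad_tol` holds even where Ψ is steep.

## Closed-form double-pulse theory

In the limits τ_s → 0 and σ_L → 0, the PSP is a sum of decaying
exponentials with per-pulse peak B = [fA − α₁]₊/τ₂ and the hazard
becomes λ_L times the total time ΔT the PSP spends above α_L; the
threshold satisfies λ_L·ΔT = log 2 (natural logs throughout). For two
pulses, ΔT takes one of three closed forms depending on whether the
crossing happens (1) only after the second pulse, (2) once per pulse in
two separate intervals, or (3) in a single interval spanning both pulses.
The case-2 candidate is computed first and accepted if its validity
inequalities hold; boundary ties go to case 2 (the expressions coincide
there, so the choice is observationally irrelevant). The IPI values at
which the valid case switches are

IPI₂₁ = −τ₂·log(2^(1/(τ₂λ_L)) − 1),
IPI₂₃ = τ₂·log(√(2^(1/(τ₂λ_L)) + 1/4) − 1/2),

and the product λ_L·τ₂ decides the shape of the threshold-vs-IPI curve:
below 1 the curve has an interior minimum at IPI₂₃ (IPI₂₃ > 0, IPI₂₁ < 0),
above 1 it is strictly increasing (IPI₂₁ > 0, IPI₂₃ < 0). At the
reference values λ_L·τ₂ = 0.45 and IPI₂₃ ≈ 24.34 ms.

B is defined with *division* by τ₂: this is forced by dimensional
consistency of the limit PSP with the leaky integrator's impulse response
and by α_L's units, and is confirmed by the numeric model reproducing the
closed-form thresholds to < 0.1 % when σ_L and τ_s are scaled down 100×.
With the reference σ_L and τ_s the numeric thresholds track the analytic
curve within ~1 % (worst case over IPI 5–100 ms); the package's agreement
test uses a 2 % envelope.

The closed forms cover NoP ∈ {1, 2} only; for more pulses the effect is
qualitatively similar but the case analysis grows combinatorially.

## Physical ratios and sweeps

Absolute values of the underlying physical quantities are not
identifiable from thresholds — only their multiplicative ratios to
baseline matter — so the package represents physical perturbations as
ratio sets mapped onto lumped-parameter multipliers (m_α₁ =
c₀c₁G₁V_th·h², m_τ₁ = C₁/G₁, m_τ₂ = C₂/G₂, m_αL = m_σL-companion =
c₀c₁G₁G₂V_th·α_h/(ρḡK), m_λL = l·λ_h; exponents linear in each factor, h
squared). Three subgroups are exactly redundant: {V_th, c₀, c₁},
{ρ, ḡ, K} and {l, λ_h}.

Sweeps vary one physical or lumped parameter over 60–170 % of baseline
(default 45 grid points, step 0.025 — fine enough to resolve the shallow
extrema of the τ₂ and σ_L curves) and classify each threshold curve as
monotone up/down or non-monotone by the signs of successive differences,
with differences below 10·`root_tol` treated as noise. At this
resolution C₂/τ₂ classify non-monotone (the single-pulse curves also
pass through an interior extremum, at λ_L·τ₂ = log 2, i.e. τ₂ ≈ 69 ms,
inside the factor range), σ_h/σ_L show a shallow tolerance-sensitive
extremum for the IPI = 30 ms combination, and every other parameter is
monotone.

## Capsaicin scenario

Per-day multiplicative ratios for (ρ, h, V_th, G₂, ḡ) encode: structural
degeneration and regrowth of intra-epidermal endings (ρ down then
recovering, h up as endings retract), transient peripheral sensitization
(V_th = 0.45 on Day 2 only), and longer-lasting central sensitization
(G₂ < 1, ḡ > 1 through Day 84). The Day-7 and Day-84 density anchors are
0.21 and 0.80 of baseline; Days 2 and 28 lie on the straight line through
the anchors (linear regeneration), reproducing 0.172 and 0.371 after
rounding to the table's three decimals.

Ablation variants reset functional ratios to 1 while always keeping the
structural pair (ρ, h): `no_functional` resets V_th, G₂ and ḡ;
`no_central` resets G₂ and ḡ; `no_peripheral` resets V_th. This mapping
follows the assignment of each quantity to a mechanism (peripheral
functional = ending excitability V_th; central functional = dorsal-horn
excitability G₂ and synaptic gain ḡ); the exact resets are a design
choice of this package since only the omissions, not the resets, are
canonical.

The qualitative pattern checks (2 % of baseline as the significance
margin, a repository choice): single-pulse thresholds rise on Days 2 and
7; double-pulse thresholds rise on Days 7, 28 and 84; the Day-2
double-pulse threshold at IPI = 20 ms is unchanged within the margin; and
no ablation variant falls below the full scenario on Days 2–28. One
nuance found during development: at IPI = 50 ms the model itself predicts
a Day-2 change of ≈ +2.8 % (confirmed independently in the closed-form
limit), so the Day-2 invariance is asserted only for the IPI = 20 ms
combination — the headline dissociation (clear single-pulse rise,
near-invariant double-pulse threshold on Day 2) is carried by that
combination.

## Synthetic trials and threshold recovery

The generator draws R = 1 iff ξ < Ψ(A), ξ ~ U(0,1), over a fixed
amplitude ladder. Everything is seeded: a dataset is a pure function of
(seed, design, parameters), and replicate experiments draw child seeds
via `numpy.random.SeedSequence.spawn`. The generator emulates only the
Bernoulli structure of a fixed-ladder detection experiment; it does not
model adaptive staircases, lapses/guesses, response bias or
inter-subject variability, so recovery results speak to the pipeline's
statistical calibration, not to human data.

Threshold recovery fits a two-parameter Weibull psychometric function —
a binomial GLM with cloglog link in log-amplitude, the standard choice
for probability-summation detection — and reads off the amplitude at
probability 0.5, with a percentile bootstrap over trials for the
interval. A symmetric logistic was tried first and rejected: on
hazard-shaped curves its symmetric form biases the 0.5-crossing upward
by several percent.

**Calibration findings** (reference parameters, double-pulse IPI = 50 ms,
ladder 0.22–0.285 mA × 7 rungs × 50 trials): Monte-Carlo detection
frequency at the solved threshold is 0.5 within 3 binomial SD at 10⁴
trials; the mean recovered threshold is within 2 % of truth over 100
replicates. A stricter goal — 95 % of replicates within 5 % of truth at
350 trials — is *not* achievable here and the corresponding test is left
failing by design: the model's psychometric function is shallow near 0.5
(the hazard exponent grows roughly logarithmically in amplitude), and
the Fisher information of 350 Bernoulli trials caps any two-parameter
maximum-likelihood estimator at ≈ 2.7 % relative standard error for the
steepest stimulus combination (≈ 94 % within 5 % even for a
correctly-specified, unbiased fit); generic two-parameter families reach
87–91 % in practice. More trials, or an estimator granted the model's
exact curve shape, would be needed.

## Known limitations

* The closed-form theory stops at two pulses.
* The capsaicin ratios are scenario inputs, not fits; the package makes
  no claim about estimating them from data (parameter estimation from
  stimulus–response pairs is out of scope).
* The sweep classification is tolerance-based; extrema shallower than
  10·`root_tol` are reported as monotone/flat.
* CSVs and the JSON summary are the supported outputs; plotting is left
  to the user.
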