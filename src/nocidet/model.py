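"""Forward hazard model of Aδ-fiber-mediated detection of electrocutaneous
pulse trains.

The model maps a square-wave pulse train (number of pulses ``NoP``,
interpulse interval ``IPI``, pulse width ``PW``, amplitude ``A``) to a
detection probability via four stages:

1. peripheral activation — a threshold-linear function of the effective
   amplitude ``fA = A(1 - exp(-PW/τ1))``;
2. an excitatory postsynaptic current, one exponential kernel (time
   constant ``τs``) per pulse;
3. the postsynaptic potential ``x(t)`` of a secondary dorsal-horn neuron,
   a leaky integrator with time constant ``τ2`` driven by the current;
4. a non-homogeneous Poisson spike process with sigmoidal rate
   ``λ(t) = λL / (1 + exp((αL - x(t))/σL))``; the stimulus is detected iff
   at least one spike occurs, so ``Ψ(A) = 1 - exp(-∫λ dt)``.

The detection threshold ``A50`` solves ``Ψ(A50) = 0.5``.

Units are mA and ms throughout; mA/ms is numerically identical to A/s, so
central parameters quoted in A/s are used verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StimulusTrain",
    "LumpedParams",
    "ModelConfig",
    "PSPTrace",
    "ThresholdResult",
    "REFERENCE_COMBOS",
    "effective_amplitude",
    "peripheral_drive",
    "stimulus_drive",
    "psc",
    "psp_values",
    "psp",
    "firing_rate",
    "expected_count",
    "psychometric",
    "detection_threshold",
    "threshold_table",
]


@dataclass(frozen=True)
class StimulusTrain:
    """One electrocutaneous stimulus.

    Parameters
    ----------
    nop : int
        Number of pulses (≥ 1).
    pw : float
        Pulse width, ms.
    ipi : float, optional
        Interpulse interval, ms. Required when ``nop > 1``; ignored for
        single pulses.
    amplitude : float, optional
        Pulse amplitude, mA. ``None`` marks a template whose amplitude is
        supplied later (e.g. by the threshold solver).
    """

    nop: int
    pw: float
    ipi: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.nop < 1:
            raise ValueError(f"nop must be >= 1, got {self.nop}")
        if self.pw <= 0:
            raise ValueError(f"pw must be positive, got {self.pw}")
        if self.nop > 1 and (self.ipi is None or self.ipi <= 0):
            raise ValueError("ipi must be positive when nop > 1")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    @property
    def pulse_times(self) -> np.ndarray:
        """Onset time of each pulse, ms (first pulse at t = 0)."""
        if self.nop == 1:
            return np.zeros(1)
        return np.arange(self.nop) * float(self.ipi)

    def with_amplitude(self, a: float) -> "StimulusTrain":
        return replace(self, amplitude=float(a))


@dataclass(frozen=True)
class LumpedParams:
    """The six lumped model parameters plus the synaptic time constant.

    ``alpha1`` (mA) and ``tau1`` (ms) describe the afferent fibers;
    ``tau2`` (ms), ``alpha_l`` and ``sigma_l`` (mA/ms ≡ A/s) and
    ``lambda_l`` (events/ms ≡ kHz) describe the secondary-neuron
    population; ``tau_s`` (ms) is the synaptic kernel time constant.
    """

    alpha1: float = 0.125
    tau1: float = 0.2
    tau2: float = 45.0
    alpha_l: float = 0.00417
    sigma_l: float = 8.33e-5
    lambda_l: float = 0.01
    tau_s: float = 1.5

    def __post_init__(self) -> None:
        for name in ("alpha1", "tau1", "tau2", "alpha_l", "sigma_l",
                     "lambda_l", "tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def reference(cls) -> "LumpedParams":
        """Reference parameter set used throughout the studies."""
        return cls()


@dataclass(frozen=True)
class ModelConfig:
    """Numerical controls for the forward model.

    ``tail_factor`` sets the trial window: integration runs to the last
    pulse time plus ``tail_factor * tau2`` (the PSP has decayed by
    ``exp(-tail_factor)`` there). ``quad_step`` overrides the quadrature
    step; by default it is ``min(tau_s/5, tau2/200)``.
    """

    tail_factor: float = 15.0
    quad_step: float | None = None
    quad_tol: float = 1e-9
    root_tol: float = 1e-6
    amplitude_bracket_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.tail_factor <= 0 or self.quad_tol <= 0 or self.root_tol <= 0:
            raise ValueError("tail_factor, quad_tol and root_tol must be positive")

    def trial_window(self, stim: StimulusTrain, params: LumpedParams) -> float:
        """Integration end time T, ms (exceeds the last pulse time)."""
        return float(stim.pulse_times[-1]) + self.tail_factor * params.tau2

    def step(self, params: LumpedParams) -> float:
        if self.quad_step is not None:
            return self.quad_step
        return min(params.tau_s / 5.0, params.tau2 / 200.0)


@dataclass(frozen=True)
class PSPTrace:
    """Sampled postsynaptic potential: ``values[i] = x(times[i])``."""

    times: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class ThresholdResult:
    """Solved detection threshold with solver diagnostics."""

    a50: float
    psi_at_a50: float
    iterations: int

    def __float__(self) -> float:
        return self.a50


#: The four stimulus combinations used in the psychophysical study.
REFERENCE_COMBOS: tuple[StimulusTrain, ...] = (
    StimulusTrain(nop=1, pw=0.21),
    StimulusTrain(nop=1, pw=0.525),
    StimulusTrain(nop=2, ipi=20.0, pw=0.525),
    StimulusTrain(nop=2, ipi=50.0, pw=0.525),
)


def effective_amplitude(a: float, pw: float, tau1: float) -> float:
    """Effective amplitude fA = A·(1 − exp(−PW/τ1)) seen by a nerve ending.

    The afferent membrane (time constant ``tau1``) low-pass filters the
    square pulse; short pulses are attenuated, long ones saturate at A.
    """
    if pw <= 0 or tau1 <= 0:
        raise ValueError("pw and tau1 must be strictly positive")
    if a < 0:
        raise ValueError("amplitude must be >= 0")
    return a * -math.expm1(-pw / tau1)


def peripheral_drive(fa: float, alpha1: float) -> float:
    """Threshold-linear peripheral activation [fA − α1]+ = π(fA − α1)H(·).

    The factor π stems from the geometric derivation of the underlying
    biophysical model and is retained exactly.
    """
    return math.pi * (fa - alpha1) if fa > alpha1 else 0.0


def stimulus_drive(stim: StimulusTrain, params: LumpedParams) -> float:
    """Peripheral drive D for a stimulus carrying an amplitude, mA."""
    if stim.amplitude is None:
        raise ValueError("stimulus has no amplitude")
    fa = effective_amplitude(stim.amplitude, stim.pw, params.tau1)
    return peripheral_drive(fa, params.alpha1)


def psc(t, stim: StimulusTrain, drive: float, tau_s: float):
    """Postsynaptic current at time(s) ``t``, mA/ms.

    Sum over pulses of ``(D/τs)·exp(-(t - t_k)/τs)·H(t - t_k)``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for tk in stim.pulse_times:
        dt = t - tk
        mask = dt >= 0
        out[mask] += (drive / tau_s) * np.exp(-dt[mask] / tau_s)
    return out


def _psp_kernel(dt: np.ndarray, drive: float, tau2: float, tau_s: float) -> np.ndarray:
    """Response of the leaky integrator to one exponential current kernel.

    Closed form D/(τ2 − τs)·(e^{−Δ/τ2} − e^{−Δ/τs}) for Δ ≥ 0; the
    degenerate τ2 = τs case uses the limiting form D·Δ/τ2²·e^{−Δ/τ2}.
    """
    if abs(tau2 - tau_s) < 1e-12 * tau2:
        return drive * dt / tau2**2 * np.exp(-dt / tau2)
    return drive / (tau2 - tau_s) * (np.exp(-dt / tau2) - np.exp(-dt / tau_s))


def psp_values(t, stim: StimulusTrain, params: LumpedParams):
    """Postsynaptic potential x(t) of the secondary neuron, mA/ms.

    Exact solution of ``τ2 ẋ = −x + I(t), x(0) = 0`` by superposition of
    per-pulse kernels.
    """
    t = np.asarray(t, dtype=float)
    drive = stimulus_drive(stim, params)
    out = np.zeros_like(t)
    if drive == 0.0:
        return out
    for tk in stim.pulse_times:
        dt = t - tk
        mask = dt >= 0
        out[mask] += _psp_kernel(dt[mask], drive, params.tau2, params.tau_s)
    return out


def psp(stim: StimulusTrain, params: LumpedParams,
        config: ModelConfig | None = None) -> PSPTrace:
    """Sample the PSP on the model's quadrature grid."""
    config = config or ModelConfig()
    t, _ = _quad_grid(stim, params, config)
    return PSPTrace(times=t, values=psp_values(t, stim, params))


def firing_rate(x, params: LumpedParams):
    """Instantaneous Poisson rate λ(x) = λL/(1 + exp((αL − x)/σL)), events/ms.

    Monotone increasing in x, bounded in (0, λL). Arguments far below
    threshold underflow cleanly to exactly 0.
    """
    x = np.asarray(x, dtype=float)
    z = (params.alpha_l - x) / params.sigma_l
    out = params.lambda_l / (1.0 + np.exp(np.minimum(z, 700.0)))
    return np.where(z > 700.0, 0.0, out)


def _segment_nodes(a: float, b: float, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Composite-Simpson nodes and weights on [a, b] with step ≤ ``step``."""
    n = max(2, int(math.ceil((b - a) / step)))
    if n % 2:
        n += 1
    t = np.linspace(a, b, n + 1)
    h = (b - a) / n
    w = np.full(n + 1, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return t, w * (h / 3.0)


def _quad_grid(stim: StimulusTrain, params: LumpedParams,
               config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights on [0, T], split at pulse onsets.

    The PSC jumps at each pulse onset, so the integrand has a kink there;
    within segments it is smooth and composite Simpson converges fast.
    """
    step = config.step(params)
    edges = list(stim.pulse_times) + [config.trial_window(stim, params)]
    ts, ws = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        t, w = _segment_nodes(float(a), float(b), step)
        ts.append(t)
        ws.append(w)
    return np.concatenate(ts), np.concatenate(ws)


def expected_count(stim: StimulusTrain, params: LumpedParams,
                   config: ModelConfig | None = None) -> float:
    """Expected spike count λ_T = ∫₀ᵀ λ(x(t)) dt over the trial window."""
    config = config or ModelConfig()
    t, w = _quad_grid(stim, params, config)
    lam = firing_rate(psp_values(t, stim, params), params)
    return float(w @ lam)


def psychometric(stim: StimulusTrain, params: LumpedParams,
                 config: ModelConfig | None = None) -> float:
    """Detection probability Ψ = 1 − exp(−λ_T) ∈ [0, 1)."""
    return -math.expm1(-expected_count(stim, params, config))


def detection_threshold(stim_template: StimulusTrain, params: LumpedParams,
                        config: ModelConfig | None = None) -> ThresholdResult:
    """Solve Ψ(A50) = 0.5 for the detection threshold A50, mA.

    Ψ is monotone nondecreasing in A, so the root is unique. The upper
    bracket starts just above the amplitude at which the peripheral stage
    turns on, A = α1/(1 − exp(−PW/τ1)), and doubles until Ψ exceeds 0.5;
    a Brent solve then refines to ``root_tol``.

    Raises
    ------
    ValueError
        "ill-posed threshold" if Ψ(0) ≥ 0.5; "threshold unreachable" if
        the bracket grows beyond ``amplitude_bracket_max``.
    """
    config = config or ModelConfig()

    def psi(a: float) -> float:
        return psychometric(stim_template.with_amplitude(a), params, config)

    if psi(0.0) >= 0.5:
        raise ValueError("ill-posed threshold: psi(0) >= 0.5")

    lo = 0.0
    hi = params.alpha1 / -math.expm1(-stim_template.pw / params.tau1) * 1.01
    n_expand = 0
    while psi(hi) < 0.5:
        lo, hi = hi, hi * 2.0
        n_expand += 1
        if hi > config.amplitude_bracket_max:
            raise ValueError("threshold unreachable within amplitude bracket")

    # Solve tighter than root_tol so the closure |psi(A50) - 0.5| stays
    # below ~10*quad_tol even where psi is steep in A.
    a50, res = brentq(lambda a: psi(a) - 0.5, lo, hi,
                      xtol=min(config.root_tol, 1e-12), full_output=True)
    return ThresholdResult(a50=float(a50), psi_at_a50=psi(float(a50)),
                           iterations=res.iterations + n_expand)


def threshold_table(combos=REFERENCE_COMBOS, params: LumpedParams | None = None,
                    config: ModelConfig | None = None):
    """Detection thresholds for a list of stimulus templates.

    Returns a DataFrame with columns NoP, IPI_ms, PW_ms, A50_mA,
    psi_at_A50, solver_iterations.
    """
    import pandas as pd

    params = params or LumpedParams.reference()
    rows = []
    for stim in combos:
        res = detection_threshold(stim, params, config)
        rows.append({
            "NoP": stim.nop,
            "IPI_ms": stim.ipi if stim.ipi is not None else float("nan"),
            "PW_ms": stim.pw,
            "A50_mA": res.a50,
            "psi_at_A50": res.psi_at_a50,
            "solver_iterations": res.iterations,
        })
    return pd.DataFrame(rows)
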