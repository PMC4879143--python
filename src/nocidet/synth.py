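"""Synthetic psychophysical trials and threshold recovery.

A trial is a Bernoulli draw: the binary response is R = 1 when a uniform
variate ξ falls below the model's detection probability Ψ(A). A dataset
is a fixed amplitude ladder with a set number of trials per rung. The
recovery harness fits a two-parameter logistic curve in log-amplitude by
maximum likelihood and reads off the amplitude at probability 0.5, with a
percentile-bootstrap interval over trials.

Randomness is fully seeded: a dataset is reproduced exactly by its
(seed, design, parameters) triple; replicate experiments draw per-replicate
child seeds from ``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import LumpedParams, ModelConfig, StimulusTrain, psychometric

__all__ = [
    "ResponseRecord",
    "ExperimentDesign",
    "ThresholdEstimate",
    "simulate_response",
    "generate_dataset",
    "estimate_threshold",
    "recovery_experiment",
]


@dataclass(frozen=True)
class ResponseRecord:
    """One simulated trial."""

    trial: int
    stimulus: StimulusTrain
    r: int
    seed: int


@dataclass(frozen=True)
class ExperimentDesign:
    """A fixed-ladder detection experiment: one stimulus template, a list
    of amplitudes, and a number of trials per amplitude."""

    template: StimulusTrain
    amplitudes: tuple[float, ...]
    trials_per_amplitude: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_amplitude < 1:
            raise ValueError("trials_per_amplitude must be >= 1")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_trials(self) -> int:
        return len(self.amplitudes) * self.trials_per_amplitude


def simulate_response(stim: StimulusTrain, params: LumpedParams,
                      config: ModelConfig | None = None,
                      rng: np.random.Generator | None = None) -> int:
    """One Bernoulli trial: R = 1 iff ξ < Ψ(A), ξ ~ U(0, 1)."""
    rng = rng if rng is not None else np.random.default_rng()
    psi = psychometric(stim, params, config)
    return int(rng.uniform() < psi)


def generate_dataset(design: ExperimentDesign, params: LumpedParams,
                     config: ModelConfig | None = None) -> pd.DataFrame:
    """Simulate the full ladder, in design order.

    Ψ is evaluated once per amplitude; the draws are vectorized. Returns
    columns trial, NoP, IPI_ms, PW_ms, A_mA, R, seed.
    """
    rng = np.random.default_rng(design.seed)
    stim = design.template
    rows = []
    trial = 0
    for a in design.amplitudes:
        psi = psychometric(stim.with_amplitude(float(a)), params, config)
        draws = (rng.uniform(size=design.trials_per_amplitude) < psi)
        for r in draws.astype(int):
            rows.append({
                "trial": trial,
                "NoP": stim.nop,
                "IPI_ms": stim.ipi if stim.ipi is not None else float("nan"),
                "PW_ms": stim.pw,
                "A_mA": float(a),
                "R": int(r),
                "seed": design.seed,
            })
            trial += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdEstimate:
    a50: float
    ci_low: float | None
    ci_high: float | None


def _fit_a50(a: np.ndarray, r: np.ndarray) -> float:
    """Two-parameter Weibull psychometric fit; amplitude at p = 0.5.

    Fits P(R=1) = 1 − exp(−exp(b0 + b1·log A)) by maximum likelihood —
    a binomial GLM with a cloglog link in log-amplitude. This is the
    natural family for probability-summation detection (the hazard
    exponent is a local power law in amplitude), so the p = 0.5 crossing
    is estimated without the asymmetry bias a symmetric logistic incurs.
    """
    import statsmodels.api as sm

    x = sm.add_constant(np.log(a))
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    fit = sm.GLM(r, x, family=fam).fit()
    b0, b1 = fit.params
    if b1 <= 0:
        raise ValueError("uninformative design: non-increasing fit")
    # p = 0.5  <=>  hazard exponent = log 2
    return float(np.exp((np.log(np.log(2.0)) - b0) / b1))


def estimate_threshold(records: pd.DataFrame, n_boot: int = 200,
                       ci_level: float = 0.95,
                       seed: int = 0) -> ThresholdEstimate:
    """Recover the detection threshold from simulated trials.

    Fits P(R=1) = logistic(b0 + b1·log A) by maximum likelihood and
    returns exp(−b0/b1), the amplitude at probability 0.5, with a
    percentile bootstrap interval over trials (``n_boot = 0`` skips it).

    Raises
    ------
    ValueError
        "uninformative design" when all responses are equal (complete
        separation) or amplitudes are not all positive.
    """
    a = records["A_mA"].to_numpy(dtype=float)
    r = records["R"].to_numpy(dtype=int)
    if np.all(r == r[0]):
        raise ValueError("uninformative design: all responses identical")
    if np.any(a <= 0):
        raise ValueError("uninformative design: non-positive amplitudes")

    a50 = _fit_a50(a, r)
    if n_boot <= 0:
        return ThresholdEstimate(a50=a50, ci_low=None, ci_high=None)

    rng = np.random.default_rng(seed)
    n = len(a)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot.append(_fit_a50(a[idx], r[idx]))
        except ValueError:
            continue  # degenerate resample
    if not boot:
        return ThresholdEstimate(a50=a50, ci_low=None, ci_high=None)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return ThresholdEstimate(a50=a50, ci_low=float(lo), ci_high=float(hi))


def recovery_experiment(params: LumpedParams, design: ExperimentDesign,
                        n_replicates: int = 100, seed: int = 0,
                        config: ModelConfig | None = None,
                        truth: float | None = None) -> dict:
    """Replicate the generate→estimate loop and summarize recovery.

    ``truth`` defaults to the numerically solved A50 of the design's
    template. Returns bias, relative bias, RMSE and the per-replicate
    estimates; replicates use independent child seeds spawned from
    ``seed``.
    """
    from .model import detection_threshold

    if truth is None:
        truth = detection_threshold(design.template, params, config).a50

    children = np.random.SeedSequence(seed).spawn(n_replicates)
    estimates = []
    n_failed = 0
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        data = generate_dataset(replace(design, seed=rep_seed), params, config)
        try:
            estimates.append(estimate_threshold(data, n_boot=0).a50)
        except ValueError:
            n_failed += 1  # degenerate replicate; reported, not hidden
    estimates = np.asarray(estimates)
    bias = float(np.mean(estimates) - truth)
    within = float(np.sum(np.abs(estimates - truth) <= 0.05 * truth))
    return {
        "truth": float(truth),
        "estimates": estimates,
        "n_failed": n_failed,
        "bias": bias,
        "relative_bias": bias / float(truth),
        "rmse": float(np.sqrt(np.mean((estimates - truth) ** 2))),
        # failed replicates count as misses
        "frac_within_5pct": within / n_replicates,
    }
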