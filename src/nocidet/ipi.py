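"""Closed-form threshold theory for double-pulse stimuli.

In the limit τs → 0 (instantaneous synaptic kernel) and σL → 0 (step-like
rate function) the model becomes analytically tractable: the PSP is a sum
of decaying exponentials of height ``B = [fA − α1]+/τ2`` and the expected
spike count is ``λL·ΔT`` where ΔT is the total time the PSP spends above
the central threshold αL. The detection threshold then satisfies the
implicit equation ``λL·ΔT = log 2``.

For two pulses, ΔT takes one of three closed forms depending on how the
PSP crosses αL:

* ``SECOND_PULSE_ONLY`` — only the summed second-pulse peak crosses;
* ``TWO_INTERVALS`` — each pulse produces its own supra-threshold interval;
* ``SPANNING_INTERVAL`` — the first pulse crosses and the PSP stays above
  threshold through the second pulse.

Whether the threshold-vs-IPI curve is monotone is decided by the product
λL·τ2: below 1 the curve has an interior minimum (at IPI₂₃), above 1 it
increases monotonically. All logarithms are natural.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .model import LumpedParams, ModelConfig, StimulusTrain, detection_threshold, peripheral_drive

__all__ = [
    "CaseLabel",
    "MonotonicityClass",
    "CaseBoundaries",
    "AnalyticThreshold",
    "limit_psp_amplitude",
    "limit_psp_values",
    "supra_threshold_intervals",
    "case_boundaries",
    "monotonicity_class",
    "analytic_threshold",
    "threshold_curve",
]


class CaseLabel(enum.Enum):
    """The three supra-threshold-interval geometries for two pulses."""

    SECOND_PULSE_ONLY = 1
    TWO_INTERVALS = 2
    SPANNING_INTERVAL = 3


class MonotonicityClass(enum.Enum):
    NON_MONOTONE = "non_monotone"
    MONOTONE_INCREASING = "monotone_increasing"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class CaseBoundaries:
    """IPI values at which the valid ΔT case switches (ms; may be negative,
    meaning the switch never occurs for physical IPIs)."""

    ipi21: float
    ipi23: float


@dataclass(frozen=True)
class AnalyticThreshold:
    """Closed-form detection threshold and the case that produced it."""

    a50: float
    b: float
    case: CaseLabel | None

    def __float__(self) -> float:
        return self.a50


def limit_psp_amplitude(fa: float, alpha1: float, tau2: float) -> float:
    """Per-pulse peak B = [fA − α1]+/τ2 of the limit PSP, mA/ms."""
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    return peripheral_drive(fa, alpha1) / tau2


def limit_psp_values(t, b: float, ipi: float, tau2: float, nop: int = 2):
    """Limit PSP x⁰(t) = B Σₖ e^{−(t−k·IPI)/τ2} H(t−k·IPI)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for k in range(nop):
        dt = t - k * ipi
        mask = dt >= 0
        out[mask] += b * np.exp(-dt[mask] / tau2)
    return out


def supra_threshold_intervals(b: float, alpha_l: float, tau2: float,
                              ipi: float) -> tuple[int, CaseLabel | None, float]:
    """Count and total length ΔT of supra-threshold intervals of x⁰(t).

    Returns ``(count, case, delta_t)`` for a double-pulse limit PSP with
    per-pulse peak ``b``. ``count`` is 0 when even the summed second-pulse
    peak B(1+e^{−IPI/τ2}) stays below αL.
    """
    q = math.exp(-ipi / tau2)
    if b * (1.0 + q) <= alpha_l:
        return 0, None, 0.0
    log_ratio = math.log(alpha_l / b)  # log(αL/B)
    l1pq = math.log1p(q)
    if b <= alpha_l:
        # crossing upon the second pulse only
        return 1, CaseLabel.SECOND_PULSE_ONLY, tau2 * (l1pq - log_ratio)
    if b * q < alpha_l:
        # two separate intervals, one per pulse
        return 2, CaseLabel.TWO_INTERVALS, tau2 * (l1pq - 2.0 * log_ratio)
    # one interval spanning both pulses
    return 1, CaseLabel.SPANNING_INTERVAL, ipi + tau2 * (l1pq - log_ratio)


def case_boundaries(tau2: float, lambda_l: float) -> CaseBoundaries:
    """IPI boundaries between ΔT cases along the threshold curve.

    ``IPI21 = −τ2·log(2^{1/(τ2 λL)} − 1)`` (case 2 → 1 switch) and
    ``IPI23 = τ2·log(√(2^{1/(τ2 λL)} + 1/4) − 1/2)`` (case 2 → 3 switch).
    Exactly one is positive unless λL·τ2 = 1, where both vanish.
    """
    if tau2 <= 0 or lambda_l <= 0:
        raise ValueError("tau2 and lambda_l must be positive")
    if tau2 * lambda_l == 1.0:
        raise ValueError("case boundaries are undefined at lambda_l*tau2 == 1")
    p = 2.0 ** (1.0 / (tau2 * lambda_l))
    ipi21 = -tau2 * math.log(p - 1.0)
    ipi23 = tau2 * math.log(math.sqrt(p + 0.25) - 0.5)
    return CaseBoundaries(ipi21=ipi21, ipi23=ipi23)


def monotonicity_class(tau2: float, lambda_l: float) -> MonotonicityClass:
    """Classify the threshold-vs-IPI curve by the product λL·τ2.

    Below 1 the curve has an interior minimum at IPI₂₃; above 1 it is
    strictly increasing; exactly 1 is flagged as the boundary case.
    """
    if tau2 <= 0 or lambda_l <= 0:
        raise ValueError("tau2 and lambda_l must be positive")
    product = tau2 * lambda_l
    if product < 1.0:
        return MonotonicityClass.NON_MONOTONE
    if product > 1.0:
        return MonotonicityClass.MONOTONE_INCREASING
    return MonotonicityClass.BOUNDARY


def _a50_from_b(b: float, pw: float, params: LumpedParams) -> float:
    """Invert B → amplitude: A = (B·τ2/π + α1)/(1 − e^{−PW/τ1})."""
    fa = b * params.tau2 / math.pi + params.alpha1
    return fa / -math.expm1(-pw / params.tau1)


def analytic_threshold(stim_template: StimulusTrain,
                       params: LumpedParams) -> AnalyticThreshold:
    """Closed-form detection threshold in the τs→0, σL→0 limit.

    Solves ``λL·ΔT = log 2`` for the per-pulse PSP peak B in the valid
    case, then maps B back to an amplitude. Supports single- and
    double-pulse stimuli; for one pulse ΔT = τ2·log(B/αL).
    """
    lam_tau = params.lambda_l * params.tau2
    target = math.log(2.0) / lam_tau  # required log(B/αL), case-dependent

    if stim_template.nop == 1:
        b = params.alpha_l * math.exp(target)
        return AnalyticThreshold(a50=_a50_from_b(b, stim_template.pw, params),
                                 b=b, case=None)
    if stim_template.nop != 2:
        raise ValueError("analytic theory covers nop in {1, 2} only")

    ipi = float(stim_template.ipi)
    q = math.exp(-ipi / params.tau2)
    l1pq = math.log1p(q)

    # Case 2 candidate first (valid at large IPI); ties go to case 2.
    b2 = params.alpha_l * math.exp((target - l1pq) / 2.0)
    if b2 >= params.alpha_l and b2 * q <= params.alpha_l:
        case, b = CaseLabel.TWO_INTERVALS, b2
    else:
        b3 = params.alpha_l * math.exp(target - ipi / params.tau2 - l1pq)
        if b3 * q >= params.alpha_l:
            case, b = CaseLabel.SPANNING_INTERVAL, b3
        else:
            b1 = params.alpha_l * math.exp(target - l1pq)
            if not (b1 <= params.alpha_l < b1 * (1.0 + q)):
                raise RuntimeError("no valid supra-threshold case found")
            case, b = CaseLabel.SECOND_PULSE_ONLY, b1
    return AnalyticThreshold(a50=_a50_from_b(b, stim_template.pw, params),
                             b=b, case=case)


def threshold_curve(ipi_grid, pw: float, params: LumpedParams,
                    config: ModelConfig | None = None, mode: str = "analytic"):
    """Detection threshold vs IPI for double-pulse stimuli.

    ``mode`` is ``"analytic"``, ``"numeric"`` or ``"both"``. Returns a
    DataFrame with columns IPI_ms, A50_analytic_mA, A50_numeric_mA,
    case_label, lambdaL_tau2_product (numeric/analytic columns are NaN
    when not requested).
    """
    import pandas as pd

    if mode not in ("analytic", "numeric", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for ipi in np.asarray(ipi_grid, dtype=float):
        stim = StimulusTrain(nop=2, ipi=float(ipi), pw=pw)
        a_ana = case = None
        if mode in ("analytic", "both"):
            res = analytic_threshold(stim, params)
            a_ana, case = res.a50, res.case.name if res.case else ""
        a_num = None
        if mode in ("numeric", "both"):
            a_num = detection_threshold(stim, params, config).a50
        rows.append({
            "IPI_ms": float(ipi),
            "A50_analytic_mA": a_ana if a_ana is not None else float("nan"),
            "A50_numeric_mA": a_num if a_num is not None else float("nan"),
            "case_label": case if case is not None else "",
            "lambdaL_tau2_product": params.lambda_l * params.tau2,
        })
    return pd.DataFrame(rows)
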