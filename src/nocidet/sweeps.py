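"""Physical → lumped parameter mapping and single-parameter threshold sweeps.

The six lumped parameters absorb some fifteen physical quantities
(conductivities, capacitances, fiber density and depth, synaptic gain,
secondary-neuron rate-function parameters, ...). Absolute physical
baselines are never needed: only multiplicative ratios relative to
baseline enter, and each ratio set maps to a multiplier on each lumped
parameter:

    m_α1 = c0·c1·G1·Vth·h²          m_τ1 = C1/G1        m_τ2 = C2/G2
    m_αL = c0·c1·G1·G2·Vth·αh/(ρ·ḡ·K)
    m_σL = c0·c1·G1·G2·Vth·σh/(ρ·ḡ·K)
    m_λL = l·λh

Three physical subgroups are redundant — {Vth, c0, c1}, {ρ, ḡ, K} and
{l, λh} — so compensating ratio changes within a subgroup leave every
lumped parameter, and hence every threshold, unchanged.

``sweep`` varies one physical or lumped parameter over a factor grid
(default 60–170 % of baseline) and solves the detection threshold for a
set of stimulus combinations at each factor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .model import (LumpedParams, ModelConfig, StimulusTrain,
                    REFERENCE_COMBOS, detection_threshold)

__all__ = [
    "PhysicalRatios",
    "LumpedMultipliers",
    "SweepSpec",
    "SweepMonotonicity",
    "PHYSICAL_PARAMETERS",
    "LUMPED_PARAMETERS",
    "lumped_multipliers",
    "apply_multipliers",
    "apply_ratios",
    "sweep",
    "classify_monotonicity",
]


@dataclass(frozen=True)
class PhysicalRatios:
    """Multiplicative perturbation factors of the physical quantities
    (baseline = 1): firing threshold ``vth``, tissue conductivity ``c0``,
    ending resistance ``c1``, ending capacitance/conductance ``cm1/gm1``,
    fiber density ``rho``, ending depth ``h``, secondary-neuron
    capacitance/conductance ``cm2/gm2``, rate-function threshold/slope
    ``alpha_h``/``sigma_h``, neuron count ``l``, single-neuron maximal rate
    ``lambda_h``, synaptic gain ``gbar``, and synaptic potential gradient
    ``k``."""

    vth: float = 1.0
    c0: float = 1.0
    c1: float = 1.0
    cm1: float = 1.0
    gm1: float = 1.0
    rho: float = 1.0
    h: float = 1.0
    cm2: float = 1.0
    gm2: float = 1.0
    alpha_h: float = 1.0
    sigma_h: float = 1.0
    l: float = 1.0
    lambda_h: float = 1.0
    gbar: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"ratio {f.name} must be > 0")


@dataclass(frozen=True)
class LumpedMultipliers:
    m_alpha1: float = 1.0
    m_tau1: float = 1.0
    m_tau2: float = 1.0
    m_alpha_l: float = 1.0
    m_sigma_l: float = 1.0
    m_lambda_l: float = 1.0


#: Physical quantities sufficient to cover all lumped parameters in sweeps.
PHYSICAL_PARAMETERS: tuple[str, ...] = (
    "vth", "cm1", "gm1", "rho", "h", "cm2", "gm2",
    "alpha_h", "sigma_h", "lambda_h",
)

LUMPED_PARAMETERS: tuple[str, ...] = (
    "alpha1", "tau1", "tau2", "alpha_l", "sigma_l", "lambda_l",
)

_EXTRA_RATIOS: tuple[str, ...] = ("c0", "c1", "l", "gbar", "k")


def lumped_multipliers(r: PhysicalRatios) -> LumpedMultipliers:
    """Map physical ratios to multiplicative factors on the lumped params."""
    central = r.c0 * r.c1 * r.gm1 * r.gm2 * r.vth / (r.rho * r.gbar * r.k)
    return LumpedMultipliers(
        m_alpha1=r.c0 * r.c1 * r.gm1 * r.vth * r.h**2,
        m_tau1=r.cm1 / r.gm1,
        m_tau2=r.cm2 / r.gm2,
        m_alpha_l=central * r.alpha_h,
        m_sigma_l=central * r.sigma_h,
        m_lambda_l=r.l * r.lambda_h,
    )


def apply_multipliers(baseline: LumpedParams, m: LumpedMultipliers) -> LumpedParams:
    """Element-wise product with the baseline; τs is untouched."""
    return replace(
        baseline,
        alpha1=baseline.alpha1 * m.m_alpha1,
        tau1=baseline.tau1 * m.m_tau1,
        tau2=baseline.tau2 * m.m_tau2,
        alpha_l=baseline.alpha_l * m.m_alpha_l,
        sigma_l=baseline.sigma_l * m.m_sigma_l,
        lambda_l=baseline.lambda_l * m.m_lambda_l,
    )


def apply_ratios(baseline: LumpedParams, r: PhysicalRatios) -> LumpedParams:
    return apply_multipliers(baseline, lumped_multipliers(r))


def _perturbed(baseline: LumpedParams, name: str, factor: float) -> LumpedParams:
    """Baseline with one physical or lumped parameter scaled by ``factor``."""
    if name in LUMPED_PARAMETERS:
        return replace(baseline, **{name: getattr(baseline, name) * factor})
    if name in PHYSICAL_PARAMETERS or name in _EXTRA_RATIOS:
        return apply_ratios(baseline, PhysicalRatios(**{name: factor}))
    raise ValueError(f"unknown parameter {name!r}")


def _default_grid() -> np.ndarray:
    # 60–170 % of reference, step 0.025 — resolves the shallow extrema of
    # the tau2/sigma_l curves.
    return np.round(np.arange(0.60, 1.70 + 1e-9, 0.025), 6)


def _default_combos(parameter: str) -> tuple[StimulusTrain, ...]:
    combos = REFERENCE_COMBOS
    if parameter in ("sigma_h", "sigma_l"):
        combos = combos + (StimulusTrain(nop=2, ipi=30.0, pw=0.525),)
    return combos


@dataclass(frozen=True)
class SweepSpec:
    """One single-parameter sweep: which parameter, over which factor grid,
    for which stimulus combinations."""

    parameter: str
    factors: np.ndarray = field(default_factory=_default_grid)
    combos: tuple[StimulusTrain, ...] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if f.ndim != 1 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("factors must be a positive ascending 1-D grid")
        object.__setattr__(self, "factors", f)
        if self.combos is None:
            object.__setattr__(self, "combos", _default_combos(self.parameter))


class SweepMonotonicity(enum.Enum):
    MONOTONE_UP = "monotone_up"
    MONOTONE_DOWN = "monotone_down"
    NON_MONOTONE = "non_monotone"
    FLAT = "flat"


def sweep(spec: SweepSpec, baseline: LumpedParams | None = None,
          config: ModelConfig | None = None) -> pd.DataFrame:
    """Detection thresholds across a single-parameter factor grid.

    Returns one row per (factor, combination) with columns parameter,
    factor, NoP, IPI_ms, PW_ms, A50_mA, unreachable. Factors at which the
    threshold is unreachable yield NaN with the flag set.
    """
    baseline = baseline or LumpedParams.reference()
    rows = []
    for factor in spec.factors:
        params = _perturbed(baseline, spec.parameter, float(factor))
        for stim in spec.combos:
            try:
                a50 = detection_threshold(stim, params, config).a50
                bad = False
            except ValueError:
                a50, bad = float("nan"), True
            rows.append({
                "parameter": spec.parameter,
                "factor": float(factor),
                "NoP": stim.nop,
                "IPI_ms": stim.ipi if stim.ipi is not None else float("nan"),
                "PW_ms": stim.pw,
                "A50_mA": a50,
                "unreachable": bad,
            })
    return pd.DataFrame(rows)


def classify_monotonicity(result: pd.DataFrame,
                          tol: float = 1e-5) -> pd.DataFrame:
    """Label each (parameter, combination) sweep curve.

    Successive differences smaller than ``tol`` (default 10× the solver
    tolerance) are treated as noise; a curve with significant differences
    of both signs is NON_MONOTONE.
    """
    out = []
    keys = ["parameter", "NoP", "IPI_ms", "PW_ms"]
    for key, grp in result.groupby(keys, dropna=False):
        a = grp.sort_values("factor")["A50_mA"].to_numpy()
        d = np.diff(a)
        d = d[np.isfinite(d)]
        up = bool(np.any(d > tol))
        down = bool(np.any(d < -tol))
        if up and down:
            label = SweepMonotonicity.NON_MONOTONE
        elif up:
            label = SweepMonotonicity.MONOTONE_UP
        elif down:
            label = SweepMonotonicity.MONOTONE_DOWN
        else:
            label = SweepMonotonicity.FLAT
        out.append(dict(zip(keys, key)) | {"monotonicity_label": label.value})
    return pd.DataFrame(out)
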