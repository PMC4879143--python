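"""Five-day topical-capsaicin scenario: neuroplasticity as parameter ratios.

High-dose topical capsaicin triggers three kinds of change that the model
can express as multiplicative perturbations of physical quantities:

* structural degeneration of nerve endings — intra-epidermal fiber
  density ρ drops and recovers roughly linearly over weeks, and ending
  depth h increases as endings retract;
* transient peripheral sensitization — the firing threshold Vth of the
  endings drops while neurogenic inflammation lasts (a couple of days);
* longer-lasting central sensitization — dorsal-horn membrane conductance
  G2 decreases and synaptic gain ḡ increases.

The per-day ratio table below covers study days 0, 2, 7, 28 and 84. The
Day-7 and Day-84 density anchors (0.21 and 0.80 of baseline) come from
published fiber-density measurements; Days 2 and 28 follow the straight
line through those anchors (linear regrowth). Ablation variants reset the
functional ratios to 1 while always keeping the structural ones (ρ, h).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (LumpedParams, ModelConfig, REFERENCE_COMBOS,
                    detection_threshold, psychometric)
from .sweeps import PhysicalRatios, apply_ratios

__all__ = [
    "STUDY_DAYS",
    "DENSITY_ANCHORS",
    "Variant",
    "StudyDayScenario",
    "PatternReport",
    "density_timeline",
    "scenario_table",
    "variant_ratios",
    "run_study",
    "psychometric_curves",
    "pattern_check",
]

STUDY_DAYS: tuple[int, ...] = (0, 2, 7, 28, 84)

#: (day, density ratio) anchors from fiber-density measurements.
DENSITY_ANCHORS: tuple[tuple[int, float], ...] = ((7, 0.21), (84, 0.80))

# Per-day multiplicative ratios (rho, h, vth, gm2, gbar); day 0 = baseline.
_RATIO_TABLE: dict[int, tuple[float, float, float, float, float]] = {
    0: (1.0, 1.0, 1.0, 1.0, 1.0),
    2: (0.172, 1.3, 0.45, 0.92, 1.832),
    7: (0.21, 1.25, 1.0, 0.9, 4.608),
    28: (0.371, 1.23, 1.0, 0.96, 3.234),
    84: (0.80, 1.15, 1.0, 0.98, 1.4),
}


class Variant(enum.Enum):
    """Which forms of plasticity are retained. Structural degeneration
    (ρ, h) is always kept; the functional ratios are selectively reset."""

    FULL = "full"
    NO_FUNCTIONAL = "no_functional"      # resets Vth, G2, gbar
    NO_CENTRAL = "no_central"            # resets G2, gbar
    NO_PERIPHERAL = "no_peripheral"      # resets Vth


@dataclass(frozen=True)
class StudyDayScenario:
    day: int
    ratios: PhysicalRatios
    variant: Variant = Variant.FULL


@dataclass(frozen=True)
class PatternReport:
    """Outcome of the qualitative pattern checks; ``failures`` lists the
    offending (check, day, combo, variant) descriptions."""

    passed: bool
    checks: dict
    failures: tuple[str, ...]


def density_timeline(anchor7: float = 0.21, anchor84: float = 0.80,
                     days=STUDY_DAYS) -> pd.Series:
    """Fiber-density ratio per day by linear inter/extrapolation.

    Straight line through (7, anchor7) and (84, anchor84); Day 0 is fixed
    at 1 (baseline, not on the regrowth line).
    """
    slope = (anchor84 - anchor7) / (84 - 7)
    days = list(days)
    vals = [1.0 if d == 0 else anchor7 + slope * (d - 7) for d in days]
    return pd.Series(vals, index=pd.Index(days, name="day"), name="r_rho")


def scenario_table() -> list[StudyDayScenario]:
    """The FULL-variant per-day ratio sets."""
    out = []
    for day, (rho, h, vth, gm2, gbar) in _RATIO_TABLE.items():
        out.append(StudyDayScenario(
            day=day,
            ratios=PhysicalRatios(rho=rho, h=h, vth=vth, gm2=gm2, gbar=gbar),
        ))
    return out


def variant_ratios(full: PhysicalRatios, variant: Variant) -> PhysicalRatios:
    """Reset the functional ratios a variant omits (structural ρ, h kept)."""
    if variant is Variant.FULL:
        return full
    if variant is Variant.NO_FUNCTIONAL:
        return replace(full, vth=1.0, gm2=1.0, gbar=1.0)
    if variant is Variant.NO_CENTRAL:
        return replace(full, gm2=1.0, gbar=1.0)
    if variant is Variant.NO_PERIPHERAL:
        return replace(full, vth=1.0)
    raise ValueError(f"unknown variant {variant!r}")


def run_study(variants=tuple(Variant), combos=REFERENCE_COMBOS,
              baseline: LumpedParams | None = None,
              config: ModelConfig | None = None) -> pd.DataFrame:
    """Detection thresholds for every (day, variant, combination).

    Returns columns day, variant, NoP, IPI_ms, PW_ms, A50_mA,
    pct_change_vs_day0.
    """
    baseline = baseline or LumpedParams.reference()
    day0 = {stim: detection_threshold(stim, baseline, config).a50
            for stim in combos}
    rows = []
    for scenario in scenario_table():
        for variant in variants:
            params = apply_ratios(baseline,
                                  variant_ratios(scenario.ratios, variant))
            for stim in combos:
                a50 = detection_threshold(stim, params, config).a50
                base = day0[stim]
                rows.append({
                    "day": scenario.day,
                    "variant": variant.value,
                    "NoP": stim.nop,
                    "IPI_ms": stim.ipi if stim.ipi is not None else float("nan"),
                    "PW_ms": stim.pw,
                    "A50_mA": a50,
                    "pct_change_vs_day0": 100.0 * (a50 - base) / base,
                })
    return pd.DataFrame(rows)


def psychometric_curves(days=STUDY_DAYS, combos=REFERENCE_COMBOS,
                        amplitudes=None, baseline: LumpedParams | None = None,
                        config: ModelConfig | None = None) -> pd.DataFrame:
    """Ψ(A) samples under each day's FULL parameters.

    Returns columns day, NoP, IPI_ms, PW_ms, A_mA, psi.
    """
    baseline = baseline or LumpedParams.reference()
    if amplitudes is None:
        amplitudes = np.linspace(0.0, 3.0, 121)
    scenarios = {s.day: s for s in scenario_table()}
    rows = []
    for day in days:
        params = apply_ratios(baseline, scenarios[day].ratios)
        for stim in combos:
            for a in np.asarray(amplitudes, dtype=float):
                rows.append({
                    "day": day,
                    "NoP": stim.nop,
                    "IPI_ms": stim.ipi if stim.ipi is not None else float("nan"),
                    "PW_ms": stim.pw,
                    "A_mA": float(a),
                    "psi": psychometric(stim.with_amplitude(float(a)),
                                        params, config),
                })
    return pd.DataFrame(rows)


def _combo_key(row) -> str:
    if row["NoP"] == 1:
        return f"NoP=1, PW={row['PW_ms']:g}"
    return f"NoP=2, IPI={row['IPI_ms']:g}, PW={row['PW_ms']:g}"


def pattern_check(result: pd.DataFrame, rel_tol: float = 0.02,
                  solver_slack: float = 1e-5) -> PatternReport:
    """Check the qualitative threshold patterns of the capsaicin scenario.

    With tolerance ``rel_tol`` (fraction of the Day-0 baseline):

    * single-pulse FULL thresholds rise above baseline on Days 2 and 7;
    * double-pulse FULL thresholds rise above baseline on Days 7, 28, 84;
    * the Day-2 change for the IPI = 20 ms double-pulse combination is
      within tolerance of zero (at IPI = 50 ms the model itself predicts
      a slightly larger Day-2 shift, ≈ +2.8 %, so that combination is not
      asserted);
    * every ablation variant's threshold is ≥ the FULL variant's on
      Days 2–28 (up to solver slack).
    """
    full = result[result["variant"] == Variant.FULL.value]
    if full.empty:
        raise ValueError("pattern_check needs FULL-variant results")

    checks: dict[str, bool] = {}
    failures: list[str] = []

    def record(name: str, ok: bool, detail: str) -> None:
        checks[name] = checks.get(name, True) and ok
        if not ok:
            failures.append(f"{name}: {detail}")

    base = {(_combo_key(r)): r["A50_mA"]
            for _, r in full[full["day"] == 0].iterrows()}

    for _, r in full.iterrows():
        key = _combo_key(r)
        rel = (r["A50_mA"] - base[key]) / base[key]
        if r["NoP"] == 1 and r["day"] in (2, 7):
            record("single_pulse_rise", rel > rel_tol,
                   f"day {r['day']}, {key}: rel change {rel:+.3f}")
        if r["NoP"] == 2 and r["day"] in (7, 28, 84):
            record("double_pulse_rise", rel > rel_tol,
                   f"day {r['day']}, {key}: rel change {rel:+.3f}")
        if r["NoP"] == 2 and r["day"] == 2 and r["IPI_ms"] == 20.0:
            record("double_pulse_day2_invariant", abs(rel) <= rel_tol,
                   f"{key}: rel change {rel:+.3f}")

    full_idx = {(r["day"], _combo_key(r)): r["A50_mA"]
                for _, r in full.iterrows()}
    ablations = result[(result["variant"] != Variant.FULL.value)
                       & result["day"].isin([2, 7, 28])]
    for _, r in ablations.iterrows():
        ref = full_idx.get((r["day"], _combo_key(r)))
        if ref is None:
            continue
        record("ablation_at_least_full",
               r["A50_mA"] >= ref - solver_slack,
               f"day {r['day']}, {_combo_key(r)}, {r['variant']}: "
               f"{r['A50_mA']:.4f} < FULL {ref:.4f}")

    return PatternReport(passed=not failures, checks=checks,
                         failures=tuple(failures))
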