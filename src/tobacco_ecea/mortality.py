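"""Premature mortality with and without policy.

Half of all deaths among continuing smokers are attributable to smoking, so
the number of premature deaths without policy is 50% of baseline smokers
plus 50% of boys under 15 expected to initiate. Quitting attenuates the
excess risk according to age at cessation: the published age-specific risk
reductions (96.9% for 15-19 year-old quitters down to 4.5% at 85+) are
interpolated with a shape-preserving monotone cubic spline, so a quitter in
age group ``a`` averts ``0.5 x curve(midpoint(a))`` deaths, and an averted
initiator — who never starts — averts the full 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .params import CAUSES, QUINTILE_LABELS, AgeGroup, MortalityParams
from .behavior import BehaviorOutcome

__all__ = [
    "AttenuationCurve",
    "MortalityOutcome",
    "fit_attenuation",
    "attenuation_from_params",
    "deaths_without_policy",
    "deaths_averted",
]


@dataclass(frozen=True)
class AttenuationCurve:
    """Monotone interpolant of excess-risk reduction vs age at quitting.

    Evaluation outside the knot range clamps to the nearest knot value.
    """

    knot_ages: np.ndarray
    knot_values: np.ndarray
    _interp: PchipInterpolator

    def __call__(self, age) -> np.ndarray:
        clamped = np.clip(age, self.knot_ages[0], self.knot_ages[-1])
        return np.asarray(self._interp(clamped))


def fit_attenuation(knots: Sequence[tuple[float, float]]) -> AttenuationCurve:
    """Fit the attenuation curve through (age, risk reduction) knots.

    A PCHIP (shape-preserving cubic) interpolant is used: it passes through
    every knot, preserves the strictly decreasing shape, and therefore stays
    inside [0, 1] wherever the knots do.
    """
    knots = sorted(knots)
    ages = np.array([a for a, _ in knots], float)
    vals = np.array([v for _, v in knots], float)
    if len(ages) < 4:
        raise ValueError("need at least 4 knots to fit the attenuation curve")
    if np.any(np.diff(vals) >= 0):
        raise ValueError("risk reductions must be strictly decreasing with age")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("risk reductions must lie in [0, 1]")
    return AttenuationCurve(ages, vals, PchipInterpolator(ages, vals))


def attenuation_from_params(params: MortalityParams,
                            age_groups: Sequence[AgeGroup]) -> AttenuationCurve:
    """Build the curve from the per-age-group risk reductions, knotted at midpoints.

    With fewer than 4 knots (degenerate synthetic inputs) a piecewise-linear
    monotone interpolant stands in for the cubic.
    """
    by_label = {g.label: g for g in age_groups}
    knots = sorted((by_label[label].midpoint, value)
                   for label, value in params.risk_reduction_by_age.items()
                   if label in by_label)
    if len(knots) >= 4:
        return fit_attenuation(knots)
    ages = np.array([a for a, _ in knots], float)
    vals = np.array([v for _, v in knots], float)

    class _Linear:
        def __call__(self, x):
            return np.interp(x, ages, vals)

    return AttenuationCurve(ages, vals, _Linear())


@dataclass
class MortalityOutcome:
    """Per-quintile premature deaths and their split by cause."""

    deaths_without: np.ndarray  # (5,)
    deaths_with: np.ndarray     # (5,)
    deaths_averted: np.ndarray  # (5,)
    by_cause: dict[str, np.ndarray]  # cause -> (5,)

    @property
    def total_averted(self) -> float:
        return float(self.deaths_averted.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "quintile": list(QUINTILE_LABELS),
            "deaths_without": self.deaths_without,
            "deaths_with": self.deaths_with,
            "deaths_averted": self.deaths_averted,
        })
        for c in CAUSES:
            df[f"averted_{c}"] = self.by_cause[c]
        return df


def deaths_without_policy(smokers: np.ndarray, future_initiators: np.ndarray,
                          attributable_fraction: float = 0.5) -> np.ndarray:
    """Premature deaths per quintile absent any policy.

    50% (the attributable fraction) of baseline smokers and of anticipated
    future initiators die prematurely of smoking-related causes.
    """
    return attributable_fraction * (smokers.sum(axis=0) + future_initiators.sum(axis=0))


def deaths_averted(behavior: BehaviorOutcome, curve: AttenuationCurve,
                   params: MortalityParams,
                   age_groups: Sequence[AgeGroup],
                   smokers: np.ndarray,
                   future_initiators: np.ndarray) -> MortalityOutcome:
    """Deaths averted by quitting (age-attenuated) and averted initiation (full).

    averted(q) = sum_a quitters(a, q) x AF x curve(midpoint(a))
               + sum_a averted_initiators(a, q) x AF
    """
    af = params.attributable_fraction
    mid = np.array([g.midpoint for g in age_groups])
    atten = curve(mid)[:, None]
    averted = (behavior.quitters * af * atten).sum(axis=0)
    averted = averted + af * behavior.averted_initiators.sum(axis=0)

    without = deaths_without_policy(smokers, future_initiators, af)
    shares = params.cause_share_array
    by_cause = {c: averted * shares[i] for i, c in enumerate(CAUSES)}
    return MortalityOutcome(
        deaths_without=without,
        deaths_with=without - averted,
        deaths_averted=averted,
        by_cause=by_cause,
    )
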