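"""Behavioural response: quitting, averted initiation and consumption change.

A policy is either a price shock (excise-tax hike fully passed into the
retail price) or a workplace smoking ban. For the price shock, the quintile-
and age-class-specific elasticity determines the total fall in cigarette
demand; half of the elasticity (``participation_share``) acts on smoking
participation — quitting among current smokers, non-initiation among boys
under 15 — and the remainder on intensity among continuing smokers. The ban
is a one-time relative reduction in smoking prevalence (9% in the base case)
with consumption unchanged.

Brand switching: a proportion ``p`` of smokers responds to the price rise by
moving to cheaper cigarettes instead of quitting or cutting back, which is
equivalent to scaling current smokers' elasticities by ``1 - p``. In this
scenario the cheap end of the market stays accessible to new smokers, so
future initiation is treated as unaffected by the price rise (no initiation
averted); set ``switching_scales_initiation=True`` to scale the initiation
response by ``1 - p`` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import (
    N_QUINTILES,
    BanAbsoluteMode,
    ElasticityTable,
    ParamBundle,
    PopulationTable,
)

__all__ = [
    "Policy",
    "BehaviorOutcome",
    "price_shock",
    "workplace_ban",
    "null_policy",
    "participation_reduction",
    "apply_brand_switching",
    "respond",
]

PRICE_SHOCK = "price_shock"
WORKPLACE_BAN = "workplace_ban"


@dataclass(frozen=True)
class Policy:
    """One policy scenario with its behavioural parameters."""

    kind: str  # "price_shock" | "workplace_ban"
    relative_price_increase: float = 0.0
    ban_relative_reduction: np.ndarray | None = None  # per quintile
    ban_absolute: BanAbsoluteMode | None = None
    switching_proportion: float = 0.0
    switching_scales_initiation: bool = False

    def __post_init__(self):
        if self.kind not in (PRICE_SHOCK, WORKPLACE_BAN):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.switching_proportion <= 1.0:
            raise ValueError("switching_proportion must lie in [0, 1]")
        if self.switching_proportion > 0 and self.kind != PRICE_SHOCK:
            raise ValueError("brand switching only applies to a price shock")


def price_shock(relative_price_increase: float = 0.75,
                switching_proportion: float = 0.0,
                switching_scales_initiation: bool = False) -> Policy:
    return Policy(PRICE_SHOCK, relative_price_increase=relative_price_increase,
                  switching_proportion=switching_proportion,
                  switching_scales_initiation=switching_scales_initiation)


def workplace_ban(relative_reduction: float | np.ndarray = 0.09,
                  absolute_mode: BanAbsoluteMode | None = None) -> Policy:
    red = np.broadcast_to(np.asarray(relative_reduction, float), (N_QUINTILES,)).copy()
    return Policy(WORKPLACE_BAN, ban_relative_reduction=red, ban_absolute=absolute_mode)


def null_policy() -> Policy:
    """A price shock of zero: no behavioural change."""
    return Policy(PRICE_SHOCK, relative_price_increase=0.0)


@dataclass
class BehaviorOutcome:
    """Per (age group x quintile) quitters, averted initiators and consumption."""

    quitters: np.ndarray            # (n_age, 5)
    averted_initiators: np.ndarray  # (n_age, 5)
    continuing: np.ndarray          # (n_age, 5)
    cigs_before: np.ndarray         # (5,) cigarettes/day per quintile
    cigs_after: np.ndarray          # (n_age, 5)
    warnings: list[str] = field(default_factory=list)


def apply_brand_switching(policy: Policy, table: ElasticityTable) -> ElasticityTable:
    """Scale every elasticity by (1 - switching proportion).

    With proportion 0.75 an average adult elasticity of -0.38 becomes -0.095
    (~ -0.10); with 0.33 it becomes ~ -0.25.
    """
    if policy.switching_proportion == 0:
        return table
    return table.scaled(1.0 - policy.switching_proportion)


def participation_reduction(elasticity: ElasticityTable, policy: Policy,
                            quintile: int, age_class: str) -> float:
    """Fraction of the group's smokers (or would-be initiators) removed by the policy.

    Price shock: |elasticity| x participation share x relative price increase,
    clamped to [0, 1]. Ban: the quintile's relative prevalence reduction,
    regardless of age class.
    """
    if policy.kind == WORKPLACE_BAN:
        return float(policy.ban_relative_reduction[quintile])
    eps = abs(elasticity.for_class(age_class)[quintile])
    red = eps * elasticity.participation_share * policy.relative_price_increase
    return float(np.clip(red, 0.0, 1.0))


def _price_shock_outcome(bundle: ParamBundle, policy: Policy,
                         pop: PopulationTable) -> BehaviorOutcome:
    elas = apply_brand_switching(policy, bundle.elasticity)
    dp = policy.relative_price_increase
    s = elas.participation_share
    n_age = len(pop.age_groups)

    eps = np.empty((n_age, N_QUINTILES))
    for i, g in enumerate(pop.age_groups):
        eps[i] = np.abs(elas.for_class(g.age_class))

    red_raw = eps * s * dp
    red = np.clip(red_raw, 0.0, 1.0)
    notes = []
    if np.any(red_raw > 1):
        notes.append(
            f"participation reduction exceeded 1 in {(red_raw > 1).sum()} cells; clamped")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=3)

    quitters = pop.smokers * red
    continuing = pop.smokers - quitters

    averted = pop.future_initiators * red
    if policy.switching_proportion > 0 and not policy.switching_scales_initiation:
        # cheaper brands keep the entry price accessible: initiation unaffected
        averted = np.zeros_like(averted)

    # Total demand falls by the full elasticity; intensity carries what quitting
    # does not ("residual"), or falls independently by the consumption half.
    base = bundle.consumption[None, :]
    if bundle.consumption_response == "independent":
        cigs_after = base * np.clip(1.0 - eps * (1.0 - s) * dp, 0.0, 1.0)
    else:
        demand = np.clip(1.0 - eps * dp, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(red < 1.0, demand / (1.0 - red), 0.0)
        cigs_after = base * np.clip(factor, 0.0, 1.0)

    return BehaviorOutcome(quitters, averted, continuing,
                           bundle.consumption.copy(), cigs_after, notes)


def _ban_outcome(bundle: ParamBundle, policy: Policy,
                 pop: PopulationTable) -> BehaviorOutcome:
    n_age = len(pop.age_groups)
    base = bundle.consumption[None, :] * np.ones((n_age, 1))

    if policy.ban_absolute is None:
        red = np.broadcast_to(policy.ban_relative_reduction[None, :],
                              pop.smokers.shape)
        quitters = pop.smokers * red
        averted = pop.future_initiators * red
        cigs_after = base.copy()
    else:
        # Absolute prevalence drop (already adjusted for worksite coverage and
        # employment) among men aged 15 to the cap; workplaces do not reach
        # children, so initiation is unchanged in this mode.
        mode = policy.ban_absolute
        quitters = np.zeros_like(pop.smokers)
        cigs_after = base.copy()
        for i, g in enumerate(pop.age_groups):
            if g.is_future or g.lower_age >= mode.age_cap:
                continue
            prev = bundle.prevalence[i]
            if prev <= 0:
                continue
            qf = min(1.0, mode.absolute_reduction_adjusted / prev)
            quitters[i] = pop.smokers[i] * qf
            cigs_after[i] = np.maximum(0.0, base[i] - mode.consumption_drop)
        averted = np.zeros_like(pop.future_initiators)

    return BehaviorOutcome(quitters, averted, pop.smokers - quitters,
                           bundle.consumption.copy(), cigs_after, [])


def respond(bundle: ParamBundle, policy: Policy,
            population: PopulationTable | None = None) -> BehaviorOutcome:
    """Convert a policy into quitters, averted initiators and consumption change."""
    if population is None:
        from .params import build_population
        population = build_population(bundle)
    if policy.kind == PRICE_SHOCK:
        out = _price_shock_outcome(bundle, policy, population)
    else:
        out = _ban_outcome(bundle, policy, population)
    # conservation holds by construction; guard against numerical drift
    assert np.allclose(out.quitters + out.continuing, population.smokers)
    return out
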