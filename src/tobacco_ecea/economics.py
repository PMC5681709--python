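"""Tax revenue and out-of-pocket treatment expenditure averted.

Annual tax revenue is cigarettes/day x 365 / pack size x price/pack x tax
share, summed over current smokers aged 15 and above. After a price shock,
revenue comes from continuing smokers at their reduced intensity and the new
price and tax share; under a ban, price and tax share stay at baseline, so
the revenue change is exactly minus the quit fraction times baseline revenue.

The expected out-of-pocket (OOP) cost per averted death mixes the four
causes of smoking-attributable death: cause share x utilization (with the
quintile multiplier, capped at 1) x treatment cost x (1 - reimbursement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    QUINTILE_LABELS,
    CostParams,
    MortalityParams,
    ParamBundle,
    PopulationTable,
    PriceTaxParams,
)
from .behavior import PRICE_SHOCK, BehaviorOutcome, Policy
from .mortality import MortalityOutcome

__all__ = [
    "RevenueOutcome",
    "OopOutcome",
    "annual_tax_per_smoker",
    "revenue",
    "expected_oop_per_averted_death",
    "oop_averted",
]

DAYS_PER_YEAR = 365


@dataclass
class RevenueOutcome:
    """Annual tax revenue per quintile, before and after policy (US$/year)."""

    revenue_before: np.ndarray  # (5,)
    revenue_after: np.ndarray   # (5,)

    @property
    def net_change(self) -> np.ndarray:
        return self.revenue_after - self.revenue_before

    @property
    def total_net_change(self) -> float:
        return float(self.net_change.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quintile": list(QUINTILE_LABELS),
            "revenue_before": self.revenue_before,
            "revenue_after": self.revenue_after,
            "net_change": self.net_change,
        })


@dataclass
class OopOutcome:
    """Out-of-pocket treatment expenditures averted per quintile (US$)."""

    oop_averted: np.ndarray                  # (5,)
    expected_oop_per_averted_death: np.ndarray  # (5,)

    @property
    def total(self) -> float:
        return float(self.oop_averted.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quintile": list(QUINTILE_LABELS),
            "oop_averted": self.oop_averted,
            "expected_oop_per_averted_death": self.expected_oop_per_averted_death,
        })


def annual_tax_per_smoker(cigs_per_day, price_per_pack: float,
                          tax_share: float, pack_size: int = 20):
    """Annual tax paid by one smoker (US$/year)."""
    return np.asarray(cigs_per_day) * DAYS_PER_YEAR / pack_size * price_per_pack * tax_share


def revenue(population: PopulationTable, behavior: BehaviorOutcome,
            prices: PriceTaxParams, policy: Policy) -> RevenueOutcome:
    """Annual tax revenue before and after the policy, per quintile.

    Revenue counts current smokers aged 15+ only (future initiators carry no
    baseline consumption). Brand switchers are continuing smokers and pay the
    post-policy price and tax share on their (unreduced) consumption; under
    the elasticity-scaling formulation they are already part of
    ``behavior.continuing`` with intensity embedded in ``cigs_after``.
    """
    adult = np.array([not g.is_future for g in population.age_groups])

    per_before = annual_tax_per_smoker(behavior.cigs_before,
                                       prices.price_before,
                                       prices.tax_share_before, prices.pack_size)
    before = (population.smokers[adult] * per_before[None, :]).sum(axis=0)

    if policy.kind == PRICE_SHOCK and policy.relative_price_increase > 0:
        # pass-through: the post-policy price follows the policy's own rise
        price = prices.price_before * (1 + policy.relative_price_increase)
        share = prices.tax_share_after
    else:
        price, share = prices.price_before, prices.tax_share_before
    per_after = annual_tax_per_smoker(behavior.cigs_after[adult], price, share,
                                      prices.pack_size)
    after = (behavior.continuing[adult] * per_after).sum(axis=0)
    return RevenueOutcome(before, after)


def expected_oop_per_averted_death(costs: CostParams,
                                   mortality: MortalityParams) -> np.ndarray:
    """Expected OOP cost per averted death, per quintile (US$).

    Mixes causes by their death shares, weights each by the probability of
    incurring treatment (utilization x quintile multiplier, capped at 1), and
    nets out insurance reimbursement.
    """
    shares = mortality.cause_share_array           # (4,)
    util = costs.utilization_matrix()              # (4, 5)
    net_cost = costs.net_cost_array()              # (4,)
    return (shares[:, None] * util * net_cost[:, None]).sum(axis=0)


def oop_averted(mort: MortalityOutcome, costs: CostParams,
                mortality_params: MortalityParams) -> OopOutcome:
    """OOP expenditures averted: deaths averted x expected OOP per averted death."""
    per_death = expected_oop_per_averted_death(costs, mortality_params)
    return OopOutcome(mort.deaths_averted * per_death, per_death)


def baseline_revenue(bundle: ParamBundle, population: PopulationTable) -> np.ndarray:
    """Convenience: annual baseline tax revenue per quintile (US$/year)."""
    adult = np.array([not g.is_future for g in population.age_groups])
    per = annual_tax_per_smoker(bundle.consumption, bundle.prices.price_before,
                                bundle.prices.tax_share_before, bundle.prices.pack_size)
    return (population.smokers[adult] * per[None, :]).sum(axis=0)
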