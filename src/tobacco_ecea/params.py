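"""Model inputs: parameter types, config loading/validation, population construction.

The analysis is driven by a single parameter file (bundled as
``data/table1_china.yaml``) holding the male population by 5-year age group,
smoking prevalence by age, the income-quintile structure, price/tax levels,
behavioural elasticities, mortality attenuation by age at quitting, disease
treatment costs, and the income distribution (mean and Gini). This module
turns that file into validated in-memory types and builds the stratified
smoker population every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CAUSES",
    "N_QUINTILES",
    "QUINTILE_LABELS",
    "AgeGroup",
    "ElasticityTable",
    "PriceTaxParams",
    "BanParams",
    "BanAbsoluteMode",
    "MortalityParams",
    "CostParams",
    "IncomeParams",
    "ParamBundle",
    "PopulationTable",
    "ConfigError",
    "load_config",
    "load_default_config",
    "default_config_path",
    "build_population",
]

#: Causes of smoking-attributable death, in the fixed order used by all arrays.
CAUSES = ("copd", "stroke", "heart", "neoplasm")

N_QUINTILES = 5
QUINTILE_LABELS = ("I", "II", "III", "IV", "V")


class ConfigError(ValueError):
    """Raised when a parameter file is malformed or violates an invariant."""


@dataclass(frozen=True)
class AgeGroup:
    """A 5-year age band; the top band is open-ended."""

    label: str
    lower_age: int
    upper_age: int | None  # None = open-ended (85+)

    @property
    def midpoint(self) -> float:
        if self.upper_age is None:
            return self.lower_age + 2.5
        return (self.lower_age + self.upper_age + 1) / 2.0

    @property
    def is_future(self) -> bool:
        """Under 15: not yet at risk of initiation, counted as future smokers."""
        return self.upper_age is not None and self.upper_age < 15

    @property
    def is_youth(self) -> bool:
        """15-24: price elasticity carries the 2x youth modifier."""
        return 15 <= self.lower_age < 25

    @property
    def age_class(self) -> str:
        if self.is_future:
            return "future"
        if self.is_youth:
            return "youth"
        return "adult"


def _parse_age_group(label: str) -> AgeGroup:
    if label.endswith("+"):
        return AgeGroup(label, int(label[:-1]), None)
    lo, hi = label.split("-")
    return AgeGroup(label, int(lo), int(hi))


@dataclass(frozen=True)
class ElasticityTable:
    """Own-price elasticity of cigarette demand per quintile and age class.

    Elasticities are stored with their sign (all non-positive). The youth and
    future values carry the doubled responsiveness of 15-24 year-olds and of
    prospective initiators; half of the total elasticity acts on participation
    (quitting) and half on consumption intensity.
    """

    adult: np.ndarray
    youth: np.ndarray
    future: np.ndarray
    participation_share: float = 0.5

    def validate(self) -> None:
        for name in ("adult", "youth", "future"):
            arr = getattr(self, name)
            if arr.shape != (N_QUINTILES,):
                raise ConfigError(f"elasticity.{name}: expected {N_QUINTILES} values")
            if np.any(arr > 0):
                raise ConfigError(f"elasticity.{name}: elasticities must be <= 0")
        if not np.allclose(self.youth, 2 * self.adult, rtol=1e-9, atol=1e-12):
            raise ConfigError("elasticity.youth must equal 2 x adult per quintile")
        if not np.allclose(self.future, self.youth, rtol=1e-9, atol=1e-12):
            raise ConfigError("elasticity.future must equal the youth values")
        if not 0.0 <= self.participation_share <= 1.0:
            raise ConfigError("elasticity.participation_share must lie in [0, 1]")

    def for_class(self, age_class: str) -> np.ndarray:
        try:
            return getattr(self, age_class)
        except AttributeError:
            raise KeyError(f"unknown age class {age_class!r}") from None

    def scaled(self, factor: float) -> "ElasticityTable":
        """Return a copy with every elasticity multiplied by ``factor``."""
        return ElasticityTable(
            adult=self.adult * factor,
            youth=self.youth * factor,
            future=self.future * factor,
            participation_share=self.participation_share,
        )


@dataclass(frozen=True)
class PriceTaxParams:
    price_before: float = 2.00
    price_after: float = 3.50
    tax_share_before: float = 0.56
    tax_share_after: float = 0.75
    pack_size: int = 20

    @property
    def relative_price_increase(self) -> float:
        return self.price_after / self.price_before - 1.0

    def validate(self) -> None:
        if not (0 < self.tax_share_before < 1 and 0 < self.tax_share_after < 1):
            raise ConfigError("prices: tax shares must lie strictly in (0, 1)")
        if self.price_after < self.price_before:
            raise ConfigError("prices: price_after must be >= price_before")
        if self.price_before <= 0 or self.pack_size <= 0:
            raise ConfigError("prices: price and pack size must be positive")


@dataclass(frozen=True)
class BanAbsoluteMode:
    """Alternative workplace-ban effect: absolute prevalence drop plus lighter smoking.

    The raw meta-analytic 3.8 percentage-point prevalence reduction is scaled
    by the share of worksites not yet covered by a ban and by the employment
    rate of working-age men, giving the population-level adjusted reduction.
    """

    absolute_reduction_raw: float = 0.038
    worksite_coverage: float = 0.31
    employed_fraction: float = 0.82
    absolute_reduction_adjusted: float = 0.022
    consumption_drop: float = 3.1  # cigarettes/day among continuing smokers
    age_cap: int = 60

    def validate(self) -> None:
        for name in ("absolute_reduction_raw", "worksite_coverage",
                     "employed_fraction", "absolute_reduction_adjusted"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"workplace_ban.absolute_mode.{name} must lie in [0, 1]")
        if self.consumption_drop < 0:
            raise ConfigError("workplace_ban.absolute_mode.consumption_drop must be >= 0")


@dataclass(frozen=True)
class BanParams:
    relative_prevalence_reduction: float = 0.09
    absolute_mode: BanAbsoluteMode = field(default_factory=BanAbsoluteMode)

    def validate(self) -> None:
        if not 0 <= self.relative_prevalence_reduction <= 1:
            raise ConfigError("workplace_ban.relative_prevalence_reduction must lie in [0, 1]")
        self.absolute_mode.validate()


@dataclass(frozen=True)
class MortalityParams:
    attributable_fraction: float
    risk_reduction_by_age: Mapping[str, float]
    cause_shares: Mapping[str, float]

    def validate(self, age_labels: Sequence[str] | None = None) -> None:
        if not 0 < self.attributable_fraction <= 1:
            raise ConfigError("mortality.attributable_fraction must lie in (0, 1]")
        vals = list(self.risk_reduction_by_age.values())
        if any(not 0 < v < 1 for v in vals):
            raise ConfigError("mortality.risk_reduction_by_age values must lie in (0, 1)")
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ConfigError(
                "mortality.risk_reduction_by_age must be strictly decreasing with age")
        if set(self.cause_shares) != set(CAUSES):
            missing = set(CAUSES) - set(self.cause_shares)
            raise ConfigError(f"mortality.cause_shares: missing or unknown causes {missing or set(self.cause_shares) - set(CAUSES)}")
        total = sum(self.cause_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mortality.cause_shares must sum to 1 (got {total})")

    @property
    def cause_share_array(self) -> np.ndarray:
        return np.array([self.cause_shares[c] for c in CAUSES])


@dataclass(frozen=True)
class CostParams:
    treatment_cost: Mapping[str, float]
    utilization: Mapping[str, float]
    quintile_utilization_multipliers: np.ndarray
    reimbursement_fraction: float

    def validate(self) -> None:
        for name, m in (("treatment_cost", self.treatment_cost),
                        ("utilization", self.utilization)):
            if set(m) != set(CAUSES):
                raise ConfigError(f"costs.{name}: must give one value per cause {CAUSES}")
        if any(v <= 0 for v in self.treatment_cost.values()):
            raise ConfigError("costs.treatment_cost values must be positive")
        if any(not 0 <= v <= 1 for v in self.utilization.values()):
            raise ConfigError("costs.utilization values must lie in [0, 1]")
        if self.quintile_utilization_multipliers.shape != (N_QUINTILES,):
            raise ConfigError("costs.quintile_utilization_multipliers: expected 5 values")
        if np.any(self.quintile_utilization_multipliers < 0):
            raise ConfigError("costs.quintile_utilization_multipliers must be >= 0")
        if not 0 <= self.reimbursement_fraction < 1:
            raise ConfigError("costs.reimbursement_fraction must lie in [0, 1)")

    def cost_array(self) -> np.ndarray:
        return np.array([self.treatment_cost[c] for c in CAUSES])

    def net_cost_array(self) -> np.ndarray:
        """Out-of-pocket cost per treated case, after insurance reimbursement."""
        return self.cost_array() * (1.0 - self.reimbursement_fraction)

    def utilization_matrix(self) -> np.ndarray:
        """(cause x quintile) probability of incurring treatment, capped at 1."""
        util = np.array([self.utilization[c] for c in CAUSES])
        return np.minimum(1.0, util[:, None] * self.quintile_utilization_multipliers[None, :])


@dataclass(frozen=True)
class IncomeParams:
    mean_income: float
    gini: float
    quintile_bounds: np.ndarray  # 4 interior boundaries, US$/year
    poverty_line_per_day: float = 1.90
    catastrophic_share: float = 0.10

    def validate(self) -> None:
        if self.mean_income <= 0:
            raise ConfigError("income.mean_income must be positive")
        if not 0 < self.gini < 1:
            raise ConfigError("income.gini must lie strictly in (0, 1)")
        if self.quintile_bounds.shape != (N_QUINTILES - 1,):
            raise ConfigError("income.quintile_bounds: expected 4 boundary incomes")
        if np.any(np.diff(self.quintile_bounds) <= 0) or self.quintile_bounds[0] <= 0:
            raise ConfigError("income.quintile_bounds must be positive and strictly increasing")
        if self.poverty_line_per_day < 0:
            raise ConfigError("income.poverty_line_per_day must be >= 0")
        if not 0 < self.catastrophic_share < 1:
            raise ConfigError("income.catastrophic_share must lie in (0, 1)")


@dataclass(frozen=True)
class ParamBundle:
    """Validated parameter set driving one analysis."""

    age_groups: tuple[AgeGroup, ...]
    males: np.ndarray                 # per age group
    prevalence: np.ndarray            # per age group; 0 under 15
    future_initiation_prevalence: float
    quintile_multipliers: np.ndarray  # relative smoking prevalence per quintile
    renormalize_multipliers: bool
    consumption: np.ndarray           # cigarettes/day per quintile
    elasticity: ElasticityTable
    prices: PriceTaxParams
    ban: BanParams
    mortality: MortalityParams
    costs: CostParams
    income: IncomeParams
    consumption_response: str = "residual"  # or "independent"

    @property
    def age_labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.age_groups)

    def validate(self, strict: bool = True) -> None:
        n = len(self.age_groups)
        if self.males.shape != (n,) or self.prevalence.shape != (n,):
            raise ConfigError("population arrays must match the number of age groups")
        if np.any(self.males < 0):
            raise ConfigError("population.males must be >= 0")
        if np.any((self.prevalence < 0) | (self.prevalence > 1)):
            raise ConfigError("smoking.prevalence values must lie in [0, 1]")
        for g, p in zip(self.age_groups, self.prevalence):
            if g.is_future and p != 0:
                raise ConfigError(f"smoking.prevalence must be 0 under age 15 (group {g.label})")
        if not 0 <= self.future_initiation_prevalence <= 1:
            raise ConfigError("smoking.future_initiation_prevalence must lie in [0, 1]")
        if self.quintile_multipliers.shape != (N_QUINTILES,):
            raise ConfigError("smoking.quintile_prevalence_multipliers: expected 5 values")
        if np.any(self.quintile_multipliers < 0):
            raise ConfigError("smoking.quintile_prevalence_multipliers must be >= 0")
        if self.consumption.shape != (N_QUINTILES,) or np.any(self.consumption < 0):
            raise ConfigError("smoking.cigarettes_per_day: expected 5 non-negative values")
        if self.consumption_response not in ("residual", "independent"):
            raise ConfigError("analysis.consumption_response must be 'residual' or 'independent'")
        self.elasticity.validate()
        self.prices.validate()
        self.ban.validate()
        self.mortality.validate()
        self.costs.validate()
        self.income.validate()
        if strict:
            self._validate_age_structure()
            missing = set(l for l, g in zip(self.age_labels, self.age_groups)
                          if not g.is_future) - set(self.mortality.risk_reduction_by_age)
            if missing:
                raise ConfigError(
                    f"mortality.risk_reduction_by_age: missing age groups {sorted(missing)}")

    def _validate_age_structure(self) -> None:
        if len(self.age_groups) != 18:
            raise ConfigError("population.age_groups: expected 18 five-year groups (0 to 85+)")
        lower = 0
        for g in self.age_groups[:-1]:
            if g.lower_age != lower or g.upper_age != lower + 4:
                raise ConfigError(
                    f"population.age_groups: groups must be contiguous 5-year bands "
                    f"(got {g.label}, expected {lower}-{lower + 4})")
            lower += 5
        last = self.age_groups[-1]
        if last.lower_age != 85 or last.upper_age is not None:
            raise ConfigError("population.age_groups: last group must be 85+")

    def effective_multipliers(self) -> np.ndarray:
        m = self.quintile_multipliers
        if self.renormalize_multipliers:
            return m / m.mean()
        return m


@dataclass(frozen=True)
class PopulationTable:
    """Male population stratified by age group and income quintile.

    ``males`` is the per-cell population (an age group's total split into
    equal fifths); ``smokers`` applies age-specific prevalence and the
    quintile prevalence multipliers; ``future_initiators`` counts boys under
    15 expected to start smoking at the assumed future prevalence.
    """

    age_groups: tuple[AgeGroup, ...]
    males: np.ndarray              # (n_age, 5)
    smokers: np.ndarray            # (n_age, 5)
    future_initiators: np.ndarray  # (n_age, 5), nonzero only under age 15

    def validate(self) -> None:
        shape = (len(self.age_groups), N_QUINTILES)
        for name in ("males", "smokers", "future_initiators"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ConfigError(f"population table: {name} has shape {arr.shape}, want {shape}")
            if np.any(arr < 0):
                raise ConfigError(f"population table: {name} has negative counts")
        for i, g in enumerate(self.age_groups):
            if g.is_future:
                if self.smokers[i].any():
                    raise ConfigError(f"population table: smokers > 0 under 15 ({g.label})")
            elif self.future_initiators[i].any():
                raise ConfigError(
                    f"population table: future initiators outside under-15 groups ({g.label})")

    @property
    def age_labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.age_groups)

    def scaled(self, k: float) -> "PopulationTable":
        return PopulationTable(self.age_groups, self.males * k,
                               self.smokers * k, self.future_initiators * k)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (age group, quintile)."""
        rows = []
        for i, g in enumerate(self.age_groups):
            for q, ql in enumerate(QUINTILE_LABELS):
                rows.append({
                    "age_group": g.label,
                    "quintile": ql,
                    "males": self.males[i, q],
                    "smokers": self.smokers[i, q],
                    "future_initiators": self.future_initiators[i, q],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config loading

def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing parameter: {where}.{key}")
    return section[key]


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "table1_china.yaml"


def load_config(path: str | Path) -> ParamBundle:
    """Load and validate a parameter file; raise :class:`ConfigError` on any defect."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")

    pop = _require(raw, "population", "")
    groups_raw = _require(pop, "age_groups", "population")
    age_groups = tuple(_parse_age_group(_require(g, "label", "population.age_groups"))
                       for g in groups_raw)
    males = np.array([float(_require(g, "males", "population.age_groups")) for g in groups_raw])

    smoking = _require(raw, "smoking", "")
    prev_map = _require(smoking, "prevalence", "smoking")
    prevalence = np.array([float(prev_map.get(g.label, 0.0)) for g in age_groups])
    for g in age_groups:
        if not g.is_future and g.label not in prev_map:
            raise ConfigError(f"missing parameter: smoking.prevalence.{g.label}")

    elas = _require(raw, "elasticity", "")
    elasticity = ElasticityTable(
        adult=np.asarray(_require(elas, "adult", "elasticity"), float),
        youth=np.asarray(_require(elas, "youth", "elasticity"), float),
        future=np.asarray(_require(elas, "future", "elasticity"), float),
        participation_share=float(elas.get("participation_share", 0.5)),
    )

    pr = _require(raw, "prices", "")
    prices = PriceTaxParams(
        price_before=float(_require(pr, "price_before", "prices")),
        price_after=float(_require(pr, "price_after", "prices")),
        tax_share_before=float(_require(pr, "tax_share_before", "prices")),
        tax_share_after=float(_require(pr, "tax_share_after", "prices")),
        pack_size=int(pr.get("pack_size", 20)),
    )

    ban_raw = _require(raw, "workplace_ban", "")
    abs_raw = ban_raw.get("absolute_mode", {})
    ban = BanParams(
        relative_prevalence_reduction=float(
            _require(ban_raw, "relative_prevalence_reduction", "workplace_ban")),
        absolute_mode=BanAbsoluteMode(
            absolute_reduction_raw=float(abs_raw.get("absolute_reduction_raw", 0.038)),
            worksite_coverage=float(abs_raw.get("worksite_coverage", 0.31)),
            employed_fraction=float(abs_raw.get("employed_fraction", 0.82)),
            absolute_reduction_adjusted=float(abs_raw.get("absolute_reduction_adjusted", 0.022)),
            consumption_drop=float(abs_raw.get("consumption_drop", 3.1)),
            age_cap=int(abs_raw.get("age_cap", 60)),
        ),
    )

    mort_raw = _require(raw, "mortality", "")
    mortality = MortalityParams(
        attributable_fraction=float(_require(mort_raw, "attributable_fraction", "mortality")),
        risk_reduction_by_age={k: float(v) for k, v in
                               _require(mort_raw, "risk_reduction_by_age", "mortality").items()},
        cause_shares={k: float(v) for k, v in
                      _require(mort_raw, "cause_shares", "mortality").items()},
    )

    cost_raw = _require(raw, "costs", "")
    costs = CostParams(
        treatment_cost={k: float(v) for k, v in
                        _require(cost_raw, "treatment_cost", "costs").items()},
        utilization={k: float(v) for k, v in
                     _require(cost_raw, "utilization", "costs").items()},
        quintile_utilization_multipliers=np.asarray(
            _require(cost_raw, "quintile_utilization_multipliers", "costs"), float),
        reimbursement_fraction=float(_require(cost_raw, "reimbursement_fraction", "costs")),
    )

    inc_raw = _require(raw, "income", "")
    income = IncomeParams(
        mean_income=float(_require(inc_raw, "mean_income", "income")),
        gini=float(_require(inc_raw, "gini", "income")),
        quintile_bounds=np.asarray(_require(inc_raw, "quintile_bounds", "income"), float),
        poverty_line_per_day=float(inc_raw.get("poverty_line_per_day", 1.90)),
        catastrophic_share=float(inc_raw.get("catastrophic_share", 0.10)),
    )

    analysis = raw.get("analysis", {})
    bundle = ParamBundle(
        age_groups=age_groups,
        males=males,
        prevalence=prevalence,
        future_initiation_prevalence=float(
            _require(smoking, "future_initiation_prevalence", "smoking")),
        quintile_multipliers=np.asarray(
            _require(smoking, "quintile_prevalence_multipliers", "smoking"), float),
        renormalize_multipliers=bool(smoking.get("renormalize_multipliers", False)),
        consumption=np.asarray(_require(smoking, "cigarettes_per_day", "smoking"), float),
        elasticity=elasticity,
        prices=prices,
        ban=ban,
        mortality=mortality,
        costs=costs,
        income=income,
        consumption_response=str(analysis.get("consumption_response", "residual")),
    )
    bundle.validate(strict=True)
    return bundle


def load_default_config() -> ParamBundle:
    """Load the bundled China parameter set."""
    return load_config(default_config_path())


# ---------------------------------------------------------------------------
# Population construction

def build_population(bundle: ParamBundle) -> PopulationTable:
    """Build the age x quintile table of males, smokers and future initiators.

    Each age group's population is split into equal fifths; smokers apply the
    age-specific prevalence and the quintile prevalence multipliers (1.14 for
    quintiles I-IV, 0.86 for V in the bundled inputs, used literally unless
    ``renormalize_multipliers`` is set).
    """
    mult = bundle.effective_multipliers()
    per_cell = bundle.males[:, None] / N_QUINTILES * np.ones((1, N_QUINTILES))
    smokers = per_cell * bundle.prevalence[:, None] * mult[None, :]
    future = np.zeros_like(smokers)
    under15 = np.array([g.is_future for g in bundle.age_groups])
    future[under15] = (per_cell[under15]
                       * bundle.future_initiation_prevalence * mult[None, :])
    table = PopulationTable(bundle.age_groups, per_cell, smokers, future)
    table.validate()
    return table
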