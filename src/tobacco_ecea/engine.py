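"""Scenario orchestration: run a policy end to end, sensitivity battery, reports.

``run_policy`` chains the pipeline — population construction, behavioural
response, mortality, tax revenue, out-of-pocket costs, financial risk
protection — and returns a :class:`ScenarioResult` holding the five outcomes
per income quintile. ``run_sensitivity_battery`` reruns the two policies
under the published alternative assumptions (flat elasticity, brand
switching, absolute ban effect, reduced bottom-quintile ban response,
alternative poverty lines).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import N_QUINTILES, QUINTILE_LABELS, ParamBundle, build_population
from .behavior import Policy, price_shock, respond, workplace_ban
from .mortality import MortalityOutcome, attenuation_from_params, deaths_averted
from .economics import OopOutcome, RevenueOutcome, oop_averted, revenue
from .financial_risk import (
    FrpOutcome,
    analytic_frp,
    income_model_from_params,
    monte_carlo_frp,
)

__all__ = [
    "ScenarioResult",
    "run_policy",
    "run_sensitivity_battery",
    "with_flat_elasticity",
    "summarize",
    "write_outputs",
]


@dataclass
class ScenarioResult:
    """Per-quintile and total outcomes of one policy scenario."""

    name: str
    policy: Policy
    mortality: MortalityOutcome
    revenue: RevenueOutcome
    oop: OopOutcome
    frp: FrpOutcome
    run_log: list[str]

    # -- per-quintile vectors -------------------------------------------------
    @property
    def deaths_averted(self) -> np.ndarray:
        return self.mortality.deaths_averted

    @property
    def revenue_change(self) -> np.ndarray:
        return self.revenue.net_change

    @property
    def oop_averted(self) -> np.ndarray:
        return self.oop.oop_averted

    @property
    def poverty_cases(self) -> np.ndarray:
        return self.frp.poverty_averted

    @property
    def catastrophic_cases(self) -> np.ndarray:
        return self.frp.catastrophic_averted

    def outcome(self, which: str) -> np.ndarray:
        return getattr(self, which)

    def total(self, which: str) -> float:
        return float(self.outcome(which).sum())

    def shares(self, which: str) -> np.ndarray:
        """Quintile shares of the total (fractions summing to 1)."""
        v = self.outcome(which)
        t = v.sum()
        if t == 0:
            return np.zeros(N_QUINTILES)
        return v / t

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "quintile": list(QUINTILE_LABELS),
            "deaths_averted": self.deaths_averted,
            "revenue_change": self.revenue_change,
            "oop_averted": self.oop_averted,
            "poverty_cases": self.poverty_cases,
            "catastrophic_cases": self.catastrophic_cases,
        })
        totals = df.drop(columns="quintile").sum()
        totals["quintile"] = "total"
        return pd.concat([df, totals.to_frame().T], ignore_index=True)


def run_policy(bundle: ParamBundle, policy: Policy,
               frp_method: str = "analytic",
               seed: int | None = None,
               poverty_line: float | None = None,
               oop_assignment: str = "mixture",
               mc_thinning: float = 1000.0,
               name: str | None = None) -> ScenarioResult:
    """Run one policy through the full pipeline. Deterministic given the seed."""
    log: list[str] = []
    pop = build_population(bundle)
    beh = respond(bundle, policy, pop)
    log.extend(beh.warnings)

    curve = attenuation_from_params(bundle.mortality, bundle.age_groups)
    mort = deaths_averted(beh, curve, bundle.mortality, bundle.age_groups,
                          pop.smokers, pop.future_initiators)
    rev = revenue(pop, beh, bundle.prices, policy)
    oop = oop_averted(mort, bundle.costs, bundle.mortality)

    model = income_model_from_params(bundle.income)
    if frp_method == "analytic":
        frp = analytic_frp(model, mort.deaths_averted, bundle.costs,
                           bundle.mortality, bundle.income,
                           poverty_line_per_day=poverty_line,
                           oop_assignment=oop_assignment)
    elif frp_method in ("mc", "monte_carlo"):
        frp = monte_carlo_frp(model, mort.deaths_averted, bundle.costs,
                              bundle.mortality, bundle.income,
                              poverty_line_per_day=poverty_line,
                              oop_assignment=oop_assignment,
                              seed=seed, thinning=mc_thinning)
        log.append(f"monte_carlo FRP: seed={seed} draws={frp.n_draws}")
    else:
        raise ValueError(f"unknown frp_method {frp_method!r}")

    return ScenarioResult(name or policy.kind, policy, mort, rev, oop, frp, log)


def with_flat_elasticity(bundle: ParamBundle, adult: float = -0.38) -> ParamBundle:
    """Replace the quintile elasticity gradient by a single flat value."""
    flat = np.full(N_QUINTILES, adult)
    elas = replace(bundle.elasticity, adult=flat, youth=2 * flat, future=2 * flat)
    return replace(bundle, elasticity=elas)


def run_sensitivity_battery(bundle: ParamBundle, seed: int | None = None,
                            frp_method: str = "analytic") -> dict[str, ScenarioResult]:
    """Base cases plus the published sensitivity scenarios, one result each."""
    def run(b, p, name, **kw):
        return run_policy(b, p, frp_method=frp_method, seed=seed, name=name, **kw)

    ban_red = bundle.ban.relative_prevalence_reduction
    bottom_red = np.full(N_QUINTILES, ban_red)
    bottom_red[0] = 0.045

    results = {
        "tax_base": run(bundle, price_shock(), "tax_base"),
        "ban_base": run(bundle, workplace_ban(ban_red), "ban_base"),
        "tax_flat_elasticity": run(with_flat_elasticity(bundle), price_shock(),
                                   "tax_flat_elasticity"),
        "tax_switching_033": run(bundle, price_shock(switching_proportion=0.33),
                                 "tax_switching_033"),
        "tax_switching_075": run(bundle, price_shock(switching_proportion=0.75),
                                 "tax_switching_075"),
        "ban_absolute": run(bundle, workplace_ban(
            ban_red, absolute_mode=bundle.ban.absolute_mode), "ban_absolute"),
        "ban_bottom_quintile_4p5": run(bundle, workplace_ban(bottom_red),
                                       "ban_bottom_quintile_4p5"),
    }
    for line in (1.00, 3.00):
        tag = str(line).replace(".", "p")
        results[f"tax_poverty_line_{tag}"] = run(
            bundle, price_shock(), f"tax_poverty_line_{tag}", poverty_line=line)
        results[f"ban_poverty_line_{tag}"] = run(
            bundle, workplace_ban(ban_red), f"ban_poverty_line_{tag}",
            poverty_line=line)
    return results


def summarize(result: ScenarioResult, config_path: str | Path | None = None) -> dict:
    """JSON-ready summary: totals, quintile values and shares, provenance."""
    outcomes = ("deaths_averted", "revenue_change", "oop_averted",
                "poverty_cases", "catastrophic_cases")
    summary = {
        "scenario": result.name,
        "policy_kind": result.policy.kind,
        "frp_method": result.frp.method,
        "totals": {k: result.total(k) for k in outcomes},
        "per_quintile": {k: result.outcome(k).tolist() for k in outcomes},
        "shares": {k: result.shares(k).tolist() for k in outcomes},
        "run_log": list(result.run_log),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if result.frp.seed is not None:
        summary["seed"] = result.frp.seed
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        summary["config"] = {"path": str(config_path), "sha256": digest}
    return summary


def write_outputs(result: ScenarioResult, outdir: str | Path,
                  config_path: str | Path | None = None) -> None:
    """Write deaths.csv, revenue.csv, oop.csv, frp.csv and summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.mortality.to_frame().to_csv(outdir / "deaths.csv", index=False)
    result.revenue.to_frame().to_csv(outdir / "revenue.csv", index=False)
    result.oop.to_frame().to_csv(outdir / "oop.csv", index=False)
    result.frp.to_frame().to_csv(outdir / "frp.csv", index=False)
    summary = summarize(result, config_path)
    summary.pop("timestamp", None)  # keep same-seed reruns byte-identical
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
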