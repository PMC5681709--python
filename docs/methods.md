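# Methods

## Scope and structure

The package models one-time policy shocks to the current Chinese male
population (males account for the overwhelming majority of smokers there;
secondhand-smoke effects on women and children are out of scope, as are
policy combinations — each scenario runs alone). There is no cohort aging,
discounting, or background cessation: behavioural change is instantaneous
and permanent, and all outcomes are lifetime totals for the people alive
today except tax revenue, which is an annual flow.

The pipeline is a chain of pure stages. `params` loads and validates the
input file and builds the age × quintile population; `behavior` turns a
policy into quitters, averted initiators and post-policy consumption;
`mortality` applies the 50% attributable-mortality rate with age-at-quitting
attenuation; `economics` prices tax revenue and out-of-pocket (OOP) costs;
`financial_risk` counts poverty and catastrophic-expenditure cases against
the gamma income model; `engine` orchestrates runs, the sensitivity battery
and reports. `synthetic` generates degenerate inputs with closed-form
outcomes and gamma income populations for testing.

## Population

Each age group's males are split into equal income-quintile fifths (the
inputs carry no age-specific income structure). Smokers per cell are
`males/5 × prevalence(age) × multiplier(quintile)` with multipliers
(1.14, 1.14, 1.14, 1.14, 0.86). These are applied literally even though
their mean is 1.084, so the implied national smoker count exceeds
`population × prevalence` by 8.4%; the published headline totals are only
reproduced under literal use, which is therefore the default
(`renormalize_multipliers: true` divides by the mean instead). Boys under
15 are assigned a future initiation prevalence of 14% — the 15–19-year-old
rate, a conservative choice since prevalence at 25–49 is far higher — and
no initiation occurs above 15.

## Behavioural response

For a price shock, the participation reduction in a cell is
`|ε| × s × Δp/p` clamped to [0, 1], with participation share `s = 0.5` and
the elasticity already doubled for 15–24-year-olds and future initiators.
Total cigarette demand in a cell falls by the full `|ε| × Δp/p`; since
quitting removes `|ε| s Δp/p` of it, continuing smokers' intensity carries
the residual factor `(1 − |ε|Δp/p) / (1 − |ε| s Δp/p)`. This
residual-demand formulation is the default because it is what an elasticity
of demand means and because it reproduces the published revenue figure
(+US$46B; the independent alternative, intensity falling by
`|ε|(1−s)Δp/p` on its own, under-delivers the demand response and yields
+US$55B). The alternative remains available as
`analysis.consumption_response: independent`.

Workplace bans remove a relative fraction of smokers (9% base case) in
every cell, future initiators included, with consumption unchanged — so the
revenue identity `net change = −0.09 × baseline revenue` holds exactly. The
absolute-effect sensitivity instead applies a 2.2-percentage-point
prevalence drop (the meta-analytic 3.8 points scaled by the 69% of
worksites without bans and 82% employment) divided by the age-specific
prevalence, restricted to ages 15–59, and cuts continuing smokers'
consumption by 3.1 cigarettes/day there; children are not in workplaces, so
initiation is unaffected in that mode.

Brand switching: a proportion `p` of smokers responds to the price rise by
trading down to cheaper brands rather than quitting or cutting back, which
is equivalent to scaling current smokers' elasticities by `1 − p`
(effective average adult elasticity −0.25 at p = 0.33, −0.10 at p = 0.75).
Because the cheap end of the market stays accessible, the switching
scenario treats youth initiation as unresponsive to the price rise — no
initiation is averted. This choice reproduces the published switching
results (14M and 5M deaths averted); pure scaling of all responses,
including initiation, is available via
`Policy(switching_scales_initiation=True)` and is the mode in which the
switching-equivalence property (switching p ≡ pre-scaled elasticities)
holds identically. Switchers remain smokers at baseline consumption and pay
the post-policy price and tax share — under the scaled-elasticity
formulation they are part of continuing demand, which is how the scenario's
large revenue gains arise.

## Mortality

Half of deaths among smokers are attributable to smoking
(`attributable_fraction`, 0.50). Deaths without policy are 0.5 × (baseline
smokers + future initiators). A quitter averts `0.5 × r(age at quitting)`,
where `r` interpolates the published risk reductions with a PCHIP
(shape-preserving monotone cubic) spline knotted at age-group midpoints
(17.5 … 87.5). PCHIP is chosen over a natural cubic spline because it
cannot overshoot: the interpolant passes through every knot, is monotone
decreasing, and stays inside [0, 1]. Evaluation outside the knot range
clamps to the nearest knot. Since quitting ages are group midpoints, the
curve only matters off-knot for synthetic checks — grouped results equal
the knot arithmetic exactly. Averted initiators never start and avert the
full 0.5 (no attenuation). Averted deaths split across causes by the fixed
shares (stroke 45.5%, heart 22.8%, neoplasm 20.4%, COPD 11.3%).

## Economics

Annual tax per smoker is `cigs/day × 365 / 20 × price/pack × tax share`;
revenue counts current smokers aged 15+ (future initiators carry no
baseline consumption). Baseline: US$2.00/pack at a 56% tax share. After the
price shock: continuing smokers at residual intensity, the post-policy
price `price_before × (1 + Δp/p)` and a 75% share; after a ban: baseline
price and share. All money is constant 2015 US$, undiscounted.

Expected OOP per averted death mixes the four causes:
`Σ share × min(1, utilization × quintile multiplier) × cost × (1 − 0.48)`,
i.e. US$1876 (quintile I) to US$2731 (quintile V); the utilization cap
never binds with the bundled values but is enforced. One averted death
corresponds to at most one treated episode.

## Financial risk protection

The gamma shape solving `G(α) = Γ(α+½)/(Γ(α+1)√π) = 0.43` is α ≈ 1.454
(G(1) = ½ recovers the exponential), scale = 3039/α; the root is found by
Brent bracketing with 1e-10 tolerance. Quintile incomes are the gamma
truncated to the published bounds (0–992, 992–1870, 1870–2973, 2973–4718,
>4718 US$/yr). Persons at risk per (quintile, cause) are
`deaths averted × cause share × capped utilization`, each facing the
cause's net OOP once (the cause-mixture default; a quintile-average OOP
assignment is available). A poverty case has income above the annualized
US$1.90 × 365 line and income − OOP below it; a catastrophic case has
OOP > 10% of income. The analytic backend evaluates these as truncated-gamma
CDF differences (the default for reports); the Monte-Carlo backend draws
one income per `thinning` persons at risk (default 1000) by inverse-CDF
sampling and rescales, reproducibly under a fixed seed. A poverty line of
zero defines no poverty state and returns zero cases.

Poverty counts are **not** monotone in the poverty line: the count is
`P(line < Y < line + OOP)`, and raising the line moves the window into
thinner parts of the income distribution — at US$3.00/day the annualized
line (1095) exceeds quintile I's upper bound (992), removing the largest
at-risk group entirely. With the bundled inputs the tax-scenario counts are
9.34M / 8.64M / 7.33M at US$1.00 / 1.90 / 3.00. What lower lines do enhance
is progressiveness (the poor-quintile share of cases). One acceptance-suite
property test asserts the opposite ordering and is expected to fail; it is
kept as documentation of this behaviour.

## Sensitivity battery

`run_sensitivity_battery` reruns: flat elasticity (−0.38 adult, −0.76
youth, all quintiles — which equalizes deaths averted across quintiles I–IV
exactly, quintile V differing only through its 0.86 prevalence multiplier);
brand switching 0.33 and 0.75; the absolute ban mode; a 4.5% bottom-quintile
ban response (initiators in that quintile included); and poverty lines
US$1.00 and US$3.00 for both policies.

## Synthetic data and what tests show

`make_degenerate_bundle` builds a single-age-group ("50–54"),
uniform-quintile, single-cause (stroke, utilization 1, no reimbursement)
bundle in which every downstream quantity has a closed form — e.g. deaths
averted = N × participation reduction × 0.5 × attenuation — used to
oracle-test each stage and the full chain. `make_income_population`
generates labelled gamma incomes whose empirical Gini (10⁶ draws) lies
within 0.005 of target, supporting parameter-recovery checks (shape
recovered within 2%). These generators emulate the *structure* of the
inputs, not China: passing tests demonstrate the arithmetic chain and the
income model, not the realism of elasticities, prevalence gradients, or
treatment costs, all of which enter only through the bundled parameter
file.

## Numerical choices and limitations

Participation reductions and utilizations are clamped (clamps logged as
warnings); consumption is floored at zero; ties and degenerate inputs
(zero prevalence, zero elasticity, zero poverty line) return exact zeros.
Monte-Carlo problem sizes default to one draw per 1000 persons at risk
(~14k draws for the tax scenario) and the examples/acceptance runs use
thinning 10–100 (~10⁶ draws), which keeps any run under a few seconds.
Known limitations mirror the model's assumptions: no tax-induced
impoverishment among continuing smokers, no supply-side (pricing-monopoly)
behaviour, no household-level accounting, no uncertainty intervals (point
estimates only), and national rather than subnational income structure.
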