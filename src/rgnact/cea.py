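"""Implementation scenarios, cost-effectiveness analysis, PSA and CEAC.

The central object is :class:`CEAModel`, built from a :class:`ParameterSet`,
a :class:`ScenarioConfig` and a life table.  ``fit()`` evaluates the
deterministic cohort model for both strategies and returns a
:class:`CEAResults` with incremental costs/effects, the ICER or a dominance
label, and a ``summary()`` table; ``fit_psa()`` adds a probabilistic
sensitivity analysis (joint parameter draws, common random numbers across
arms) from which cost-effectiveness acceptability curves are computed with
the net-monetary-benefit rule ``lambda*dE - dC > 0``.

Scenario semantics: a fraction of the national target population receives
the response-guided strategy (implementation uptake net of MRI
contraindications); everyone else receives conventional treatment.  The
comparator cohort is fully conventional, so the incremental quantities scale
linearly with the guided fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import (
    ArmOutcome,
    LifeTable,
    MarkovTrace,
    ModelInputs,
    conventional_arm,
    rescale_tps,
    rg_arm,
    run_cohort,
    sample_inputs,
)
from .params import ContraindicationSet, ParameterSet

__all__ = [
    "ScenarioConfig",
    "CEAModel",
    "CEAResults",
    "PSAResult",
    "excluded_for_contraindications",
    "mix_scenario",
    "deterministic_cea",
    "run_psa",
    "ceac",
    "hr_sensitivity",
    "WTP_THRESHOLD",
]

WTP_THRESHOLD = 20_000.0  # Euro per QALY willingness-to-pay threshold


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """An implementation scenario of the guided strategy.

    ``current_scans`` overrides the number of monitored patients for the
    current-implementation scenario (a national estimate external to the
    model); when absent the count is ``uptake * n_target * (1 - excluded
    fraction)``.
    """

    name: str
    uptake: float
    n_target: int = 6306
    hospitals: int = 113
    scanners: int = 148
    current_scans: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.uptake <= 1.0:
            raise ValueError(f"uptake must lie in [0, 1], got {self.uptake}")
        if self.n_target < 0 or self.hospitals < 0 or self.scanners < 0:
            raise ValueError("scenario counts must be >= 0")

    @classmethod
    def current(cls, uptake: float = 0.042, current_scans: int = 218,
                n_target: int = 6306) -> "ScenarioConfig":
        return cls("current", uptake, n_target, hospitals=16, scanners=31,
                   current_scans=current_scans)

    @classmethod
    def full(cls, n_target: int = 6306) -> "ScenarioConfig":
        return cls("full", 1.0, n_target, hospitals=113, scanners=148)

    @classmethod
    def with_uptake(cls, uptake: float, n_target: int = 6306) -> "ScenarioConfig":
        return cls(f"uptake={uptake:g}", uptake, n_target, hospitals=113, scanners=148)


def excluded_for_contraindications(n: float, contraindications, method: str = "additive") -> float:
    """Expected number of patients excluded for MRI contraindications.

    ``method="additive"`` sums the prevalences (the default; reproduces the
    published exclusion count); ``method="complement-product"`` uses
    ``1 - prod(1 - p_i)``.  Returns the unrounded expectation; reports floor
    it to whole patients.
    """
    if n < 0:
        raise ValueError("population size must be >= 0")
    if isinstance(contraindications, ContraindicationSet):
        prevalences = [getattr(contraindications, c).mean
                       for c in contraindications.exclusion_components]
    else:
        prevalences = list(contraindications)
    if method == "additive":
        frac = sum(prevalences)
    elif method == "complement-product":
        frac = 1.0 - math.prod(1.0 - p for p in prevalences)
    else:
        raise ValueError(f"unknown method {method!r}")
    if frac > 1.0:
        raise ValueError(f"contraindication prevalences sum to {frac} > 1")
    return min(n * frac, n)


def mix_scenario(scenario: ScenarioConfig, inputs) -> tuple[float, float]:
    """Population weights over (guided, conventional) treatment.

    The guided weight is ``uptake * (1 - contraindicated fraction)``; when the
    scenario pins an externally estimated scan count (current scenario) that
    count defines the guided fraction directly.
    """
    contra = inputs.contraindication_sum if hasattr(inputs, "contraindication_sum") else float(inputs)
    if scenario.current_scans is not None:
        w_rg = scenario.current_scans / scenario.n_target
    else:
        w_rg = scenario.uptake * (1.0 - contra)
    if not 0.0 <= w_rg <= 1.0:
        raise ValueError(f"guided fraction {w_rg} outside [0, 1]")
    return w_rg, 1.0 - w_rg


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

def icer_label(delta_cost: float, delta_effect: float, wtp: float = WTP_THRESHOLD):
    """(icer, label, cost_effective) for the guided strategy vs conventional.

    ``dominant`` when it saves money and gains QALYs; ``dominated`` in the
    opposite quadrant; otherwise the ICER.  The accept decision uses the
    net-monetary-benefit rule ``wtp*dE - dC > 0`` (ties count as not
    cost-effective).
    """
    nmb = wtp * delta_effect - delta_cost
    cost_effective = nmb > 0.0
    if delta_cost < 0 and delta_effect > 0:
        return None, "dominant", cost_effective
    if delta_cost > 0 and delta_effect < 0:
        return None, "dominated", cost_effective
    if delta_effect == 0:
        return None, ("cost-saving" if delta_cost < 0 else "no difference" if delta_cost == 0 else "costlier"), cost_effective
    return delta_cost / delta_effect, "icer", cost_effective


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental outcomes of the probabilistic analysis."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int
    hr_mode: str
    scenario: str

    @property
    def n_draws(self) -> int:
        return self.delta_cost.size

    def prob_cost_effective(self, wtp: float = WTP_THRESHOLD) -> float:
        nmb = wtp * self.delta_effect - self.delta_cost
        return float(np.mean(nmb > 0.0))

    def ceac(self, thresholds=None) -> pd.DataFrame:
        return ceac(self, thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_qaly": self.delta_effect})


@dataclass
class CEAResults:
    """Deterministic CEA results for one scenario, with optional PSA."""

    scenario: ScenarioConfig
    rg_outcome: ArmOutcome
    conventional_outcome: ArmOutcome
    w_rg: float
    wtp: float = WTP_THRESHOLD
    horizon: int = 5
    discount_cost: float = 0.04
    discount_effect: float = 0.015
    traces: dict = field(default_factory=dict)
    psa: PSAResult | None = None

    # incremental quantities are per patient of the scenario cohort vs an
    # all-conventional cohort: delta = w_rg * (guided - conventional)
    def _delta(self, attr: str) -> float:
        return self.w_rg * (getattr(self.rg_outcome, attr) - getattr(self.conventional_outcome, attr))

    @property
    def delta_cost(self) -> float:
        return self._delta("cost_disc")

    @property
    def delta_qaly(self) -> float:
        return self._delta("qaly_disc")

    @property
    def delta_ly(self) -> float:
        return self._delta("ly_disc")

    @property
    def delta_cost_undisc(self) -> float:
        return self._delta("cost")

    @property
    def delta_qaly_undisc(self) -> float:
        return self._delta("qaly")

    @property
    def icer(self):
        return icer_label(self.delta_cost, self.delta_qaly, self.wtp)[0]

    @property
    def label(self) -> str:
        return icer_label(self.delta_cost, self.delta_qaly, self.wtp)[1]

    @property
    def cost_effective(self) -> bool:
        return icer_label(self.delta_cost, self.delta_qaly, self.wtp)[2]

    def scenario_outcome(self) -> ArmOutcome:
        """Expected per-patient outcome of the mixed scenario cohort."""
        return self.rg_outcome.blend(self.conventional_outcome, self.w_rg)

    def summary(self) -> str:
        rows = []
        mix = self.scenario_outcome()
        for label, o in (
            (f"scenario cohort ({self.w_rg:.1%} guided)", mix),
            ("RG-NACT arm", self.rg_outcome),
            ("conventional-NACT arm", self.conventional_outcome),
        ):
            rows.append(
                f"{label:<38} cost {o.cost_disc:>10.2f}  LY {o.ly_disc:6.3f}  QALY {o.qaly_disc:6.3f}"
            )
        icer, label, ce = icer_label(self.delta_cost, self.delta_qaly, self.wtp)
        lines = [
            f"Cost-effectiveness analysis -- scenario '{self.scenario.name}' "
            f"(n={self.scenario.n_target}, horizon {self.horizon} y, "
            f"discount {self.discount_cost:.1%}/{self.discount_effect:.1%})",
            "-" * 78,
            *rows,
            "-" * 78,
            f"incremental cost per patient   {self.delta_cost:>10.2f} EUR",
            f"incremental QALYs per patient  {self.delta_qaly:>10.4f}",
            f"incremental LYs per patient    {self.delta_ly:>10.4f}",
            f"decision at {self.wtp:,.0f} EUR/QALY    "
            + (f"{label}" if icer is None else f"ICER = {icer:,.0f} EUR/QALY")
            + (" (cost-effective)" if ce else " (not cost-effective)"),
        ]
        if self.psa is not None:
            lines.append(
                f"PSA ({self.psa.n_draws} draws, seed {self.psa.seed}, hr_mode={self.psa.hr_mode}): "
                f"P(cost-effective at {self.wtp:,.0f}) = {self.psa.prob_cost_effective(self.wtp):.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        icer, label, ce = icer_label(self.delta_cost, self.delta_qaly, self.wtp)
        d = {
            "scenario": self.scenario.name,
            "w_rg": self.w_rg,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "delta_cost_undiscounted": self.delta_cost_undisc,
            "delta_qaly_undiscounted": self.delta_qaly_undisc,
            "icer": icer,
            "label": label,
            "cost_effective_at_wtp": ce,
            "wtp": self.wtp,
            "arms": {
                name: {
                    "cost": o.cost_disc, "ly": o.ly_disc, "qaly": o.qaly_disc,
                    "cost_undiscounted": o.cost, "ly_undiscounted": o.ly,
                    "qaly_undiscounted": o.qaly, "events": o.events,
                }
                for name, o in (
                    ("rg_nact", self.rg_outcome),
                    ("conventional_nact", self.conventional_outcome),
                )
            },
        }
        if self.psa is not None:
            d["psa"] = {
                "n_draws": self.psa.n_draws,
                "seed": self.psa.seed,
                "hr_mode": self.psa.hr_mode,
                "prob_cost_effective": self.psa.prob_cost_effective(self.wtp),
            }
        return d


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CEAModel:
    """Decision model comparing guided vs conventional neoadjuvant therapy.

    Parameters
    ----------
    params : ParameterSet
    scenario : ScenarioConfig
    life_table : LifeTable, optional
        Other-cause mortality; defaults to the bundled synthetic table.
    horizon, discount_cost, discount_effect :
        Model horizon in 1-year cycles and Dutch-guideline discount rates
        (4% costs, 1.5% effects).
    bc_death_indexing : {"since-relapse", "model-time"}
        Whether breast-cancer-death probabilities after relapse are indexed
        by time since relapse (tunnel states; default) or by model time.
    hr_mode : {"resample", "fixed"}
        PSA handling of the conventional arm: re-derive its transition
        probabilities from sampled hazard ratios, or keep them fixed.
    """

    def __init__(
        self,
        params: ParameterSet,
        scenario: ScenarioConfig,
        life_table: LifeTable | None = None,
        horizon: int = 5,
        discount_cost: float = 0.04,
        discount_effect: float = 0.015,
        wtp: float = WTP_THRESHOLD,
        bc_death_indexing: str = "since-relapse",
        hr_mode: str = "resample",
    ):
        if life_table is None:
            from .synthetic import synthetic_life_table

            life_table = synthetic_life_table()
        self.params = params
        self.scenario = scenario
        self.life_table = life_table
        self.horizon = horizon
        self.discount_cost = discount_cost
        self.discount_effect = discount_effect
        self.wtp = wtp
        self.bc_death_indexing = bc_death_indexing
        self.hr_mode = hr_mode

    @classmethod
    def from_config(cls, config_source, scenario: ScenarioConfig, **kwargs) -> "CEAModel":
        from .params import load_parameters

        return cls(load_parameters(config_source), scenario, **kwargs)

    # -- evaluation at one parameter point ---------------------------------
    def _arm_outcomes(self, inputs: ModelInputs, with_traces: bool = False):
        kw = dict(
            life_table=self.life_table, horizon=self.horizon,
            discount_cost=self.discount_cost, discount_effect=self.discount_effect,
        )
        rg_trace, rg = run_cohort(rg_arm(inputs, self.bc_death_indexing), inputs, **kw)
        conv_trace, conv = run_cohort(conventional_arm(inputs, self.bc_death_indexing), inputs, **kw)
        traces = {"rg_nact": rg_trace, "conventional_nact": conv_trace} if with_traces else {}
        return rg, conv, traces

    def fit(self) -> CEAResults:
        """Deterministic base-case evaluation at the parameter means."""
        inputs = ModelInputs.from_means(self.params)
        rg, conv, traces = self._arm_outcomes(inputs, with_traces=True)
        w_rg, _ = mix_scenario(self.scenario, inputs)
        return CEAResults(
            scenario=self.scenario, rg_outcome=rg, conventional_outcome=conv,
            w_rg=w_rg, wtp=self.wtp, horizon=self.horizon,
            discount_cost=self.discount_cost, discount_effect=self.discount_effect,
            traces=traces,
        )

    def fit_psa(self, n_draws: int = 10_000, seed: int = 20160905,
                results: CEAResults | None = None) -> CEAResults:
        """Deterministic fit plus a PSA with ``n_draws`` joint parameter draws."""
        res = results if results is not None else self.fit()
        res.psa = run_psa(
            self.scenario, self.params, n_draws=n_draws, seed=seed,
            life_table=self.life_table, horizon=self.horizon,
            discount_cost=self.discount_cost, discount_effect=self.discount_effect,
            bc_death_indexing=self.bc_death_indexing, hr_mode=self.hr_mode,
        )
        return res


def deterministic_cea(scenario: ScenarioConfig, params: ParameterSet,
                      life_table: LifeTable | None = None, **kwargs) -> CEAResults:
    """Functional wrapper: deterministic CEA for one scenario."""
    return CEAModel(params, scenario, life_table, **kwargs).fit()


# ---------------------------------------------------------------------------
# PSA / CEAC
# ---------------------------------------------------------------------------

def run_psa(
    scenario: ScenarioConfig,
    params: ParameterSet,
    n_draws: int = 10_000,
    seed: int = 20160905,
    life_table: LifeTable | None = None,
    horizon: int = 5,
    discount_cost: float = 0.04,
    discount_effect: float = 0.015,
    bc_death_indexing: str = "since-relapse",
    hr_mode: str = "resample",
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    One joint draw of every parameter distribution per iteration, shared by
    both arms (common random numbers), recording the per-patient incremental
    cost and QALYs of the scenario cohort versus an all-conventional cohort.
    Identical seeds give bit-identical draw sequences.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    if life_table is None:
        from .synthetic import synthetic_life_table

        life_table = synthetic_life_table()
    rng = np.random.default_rng(int(seed))
    draws = sample_inputs(params, rng, n_draws, hr_mode=hr_mode)
    kw = dict(life_table=life_table, horizon=horizon,
              discount_cost=discount_cost, discount_effect=discount_effect)

    delta_cost = np.empty(n_draws)
    delta_effect = np.empty(n_draws)
    for i, inputs in enumerate(draws):
        _, rg = run_cohort(rg_arm(inputs, bc_death_indexing), inputs, **kw)
        _, conv = run_cohort(conventional_arm(inputs, bc_death_indexing), inputs, **kw)
        w_rg, _ = mix_scenario(scenario, inputs)
        delta_cost[i] = w_rg * (rg.cost_disc - conv.cost_disc)
        delta_effect[i] = w_rg * (rg.qaly_disc - conv.qaly_disc)
    return PSAResult(delta_cost=delta_cost, delta_effect=delta_effect,
                     seed=int(seed), hr_mode=hr_mode, scenario=scenario.name)


def ceac(psa: PSAResult, thresholds=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay ``lambda`` the probability that the guided
    strategy is optimal: the fraction of draws with positive net monetary
    benefit ``lambda*dE - dC`` (ties count as not cost-effective).
    """
    if psa.n_draws == 0:
        raise ValueError("CEAC requires at least one PSA draw")
    if thresholds is None:
        thresholds = np.arange(0.0, 50_001.0, 1_000.0)
    thresholds = np.asarray(thresholds, float)
    nmb = thresholds[:, None] * psa.delta_effect[None, :] - psa.delta_cost[None, :]
    prob = (nmb > 0.0).mean(axis=1)
    return pd.DataFrame({"threshold": thresholds, "probability": prob})


# ---------------------------------------------------------------------------
# hazard-ratio sensitivity analysis
# ---------------------------------------------------------------------------

def hr_sensitivity(
    scenario: ScenarioConfig,
    params: ParameterSet,
    taus_rfs=None,
    taus_bcss=None,
    life_table: LifeTable | None = None,
    two_way: bool = False,
    wtp: float = WTP_THRESHOLD,
    **model_kwargs,
) -> pd.DataFrame:
    """One-/two-way sensitivity of the CEA to the two hazard ratios.

    The conventional arm's relapse (RFS) and breast-cancer-death (BCSS)
    probabilities are re-derived for each grid value via the
    hazard-rescaling pathway; ``tau`` equal to the base-case hazard ratio
    reproduces the base case.  The two-way grid is the outer product of the
    one-way grids.  Each row records incremental cost/QALYs, the ICER (or
    dominance label) and the cost-effectiveness flag at ``wtp``.
    """
    base = ModelInputs.from_means(params)
    tau_rfs_base = params.transitions.hr_rfs.mean
    tau_bcss_base = params.transitions.hr_bcss.mean
    if taus_rfs is None and taus_bcss is None:
        taus_rfs = np.arange(0.1, 1.51, 0.1)
    for grid in (taus_rfs, taus_bcss):
        if grid is not None and np.any(np.asarray(grid, float) <= 0):
            raise ValueError("hazard ratios must be positive")

    if two_way:
        if taus_rfs is None or taus_bcss is None:
            raise ValueError("two-way analysis needs both grids")
        points = [(r, b) for r in taus_rfs for b in taus_bcss]
    else:
        points = []
        if taus_rfs is not None:
            points += [(r, None) for r in taus_rfs]
        if taus_bcss is not None:
            points += [(None, b) for b in taus_bcss]

    model = CEAModel(params, scenario, life_table, wtp=wtp, **model_kwargs)
    rows = []
    for tau_r, tau_b in points:
        inputs = replace(
            base,
            relapse_conventional=(
                rescale_tps(base.relapse_conventional, tau_r, tau_rfs_base)
                if tau_r is not None else base.relapse_conventional
            ),
            bc_death_conventional=(
                rescale_tps(base.bc_death_conventional, tau_b, tau_bcss_base)
                if tau_b is not None else base.bc_death_conventional
            ),
        )
        rg, conv, _ = model._arm_outcomes(inputs)
        w_rg, _ = mix_scenario(scenario, inputs)
        d_cost = w_rg * (rg.cost_disc - conv.cost_disc)
        d_qaly = w_rg * (rg.qaly_disc - conv.qaly_disc)
        icer, label, ce = icer_label(d_cost, d_qaly, wtp)
        rows.append({
            "hr_rfs": np.nan if tau_r is None else float(tau_r),
            "hr_bcss": np.nan if tau_b is None else float(tau_b),
            "delta_cost": d_cost,
            "delta_qaly": d_qaly,
            "icer": np.nan if icer is None else icer,
            "label": label,
            "cost_effective": ce,
        })
    return pd.DataFrame(rows)
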