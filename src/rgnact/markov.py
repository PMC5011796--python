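"""Five-year Markov cohort engine for one treatment arm.

States are disease-free (DFS), relapse (R, tracked by years since relapse via
tunnel sub-states) and death (split into breast-cancer and other-cause).
Cycles are one year; transitions and accruals happen at cycle end with no
half-cycle correction.  Per-cycle accruals use start-of-cycle occupancy;
transition costs (relapse episode, breast-cancer death episode) are charged
in the cycle in which the transition occurs.

Year-1 specifics: the whole cohort sits in DFS receiving chemotherapy; the
cycle utility is the chemotherapy utility, substituted by toxicity utilities
(and, in monitored arms, the incidental-finding anxiety utility) for the
affected fractions; regimen, toxicity-treatment, monitoring and
incidental-finding confirmation costs accrue here.  Year-5: long-term
AML/MDS toxicity (cost and utility) applies to patients alive in that cycle.
Other-cause mortality applies to every alive state from a life table, ages
advancing with model time from the cohort starting age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import ParameterSet

__all__ = [
    "LifeTable",
    "ModelInputs",
    "Subgroup",
    "ArmSpec",
    "MarkovTrace",
    "ArmOutcome",
    "ToxicityEvent",
    "toxicity_burden",
    "expected_year1_utility",
    "discounted_sum",
    "run_cohort",
    "rg_arm",
    "conventional_arm",
    "rescale_tps",
    "sample_inputs",
]

START_AGE = 50
AML_CYCLE = 5  # long-term toxicity strikes in model year 5
YEAR1_TOXICITIES = ("vomiting", "neutropenia", "hfs", "desquamation", "chf")


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause (non-breast-cancer) mortality probability by age."""

    ages: np.ndarray
    mortality: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, float)
        q = np.asarray(self.mortality, float)
        if ages.size != q.size or ages.size == 0:
            raise ValueError("life table needs matching, non-empty age/mortality columns")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("life-table mortality probabilities must lie in [0, 1]")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "mortality", q)

    def q(self, age: float) -> float:
        """Mortality at ``age``; clamped to the table's range."""
        idx = int(np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, self.ages.size - 1))
        return float(self.mortality[idx])

    @classmethod
    def zero(cls, ages=range(START_AGE, START_AGE + 6)) -> "LifeTable":
        ages = np.asarray(list(ages), float)
        return cls(ages=ages, mortality=np.zeros_like(ages))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(float), mortality=df["annual_mortality"].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_mortality": self.mortality})


# ---------------------------------------------------------------------------
# realised model inputs (one point in parameter space)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelInputs:
    """A fully realised (scalar) set of model inputs.

    Produced either from the parameter means (deterministic base case) or
    from one joint draw of all parameter distributions (one PSA iteration).
    """

    monitoring: np.ndarray  # weights over true-fav, true-unfav, false-fav, false-unfav
    tox_prob: dict  # toxicity -> {block: probability}, blocks ac3/dc3/ac6
    tox_util: dict
    tox_cost: dict
    relapse_false: np.ndarray
    relapse_conventional: np.ndarray
    bc_death_false: np.ndarray
    bc_death_conventional: np.ndarray
    hr_rfs: float
    hr_bcss: float
    u_chemo: float
    u_dfs: float
    u_relapse: float
    u_anxiety: float
    u_aml: float
    c_regimen_6xac: float
    c_regimen_acdc: float
    c_monitoring: float
    c_confirm: float
    c_dfs_annual: float
    c_relapse_episode: float
    c_bc_death: float
    p_incidental: float
    p_malignant: float
    contraindication_sum: float
    p_nsf: float
    p_ats: float
    uptake_current: float

    @classmethod
    def from_means(cls, pset: ParameterSet) -> "ModelInputs":
        t = pset.transitions
        tox = pset.toxicity
        return cls(
            monitoring=pset.monitoring.means.copy(),
            tox_prob={k: {b: p.mean for b, p in blocks.items()} for k, blocks in tox.prob.items()},
            tox_util={k: u.mean for k, u in tox.utility.items()},
            tox_cost={k: c.mean for k, c in tox.cost.items()},
            relapse_false=np.array([p.mean for p in t.relapse_false]),
            relapse_conventional=np.array([p.mean for p in t.relapse_conventional]),
            bc_death_false=np.array([p.mean for p in t.bc_death_false]),
            bc_death_conventional=np.array([p.mean for p in t.bc_death_conventional]),
            hr_rfs=t.hr_rfs.mean,
            hr_bcss=t.hr_bcss.mean,
            u_chemo=pset.utilities.chemotherapy.mean,
            u_dfs=pset.utilities.dfs.mean,
            u_relapse=pset.utilities.relapse.mean,
            u_anxiety=pset.utilities.anxiety.mean,
            u_aml=pset.utilities.aml_mds.mean,
            c_regimen_6xac=pset.costs.regimen_6xac_total,
            c_regimen_acdc=pset.costs.regimen_acdc_total,
            c_monitoring=pset.costs.monitoring_total,
            c_confirm=pset.costs.confirm_incidental.mean,
            c_dfs_annual=pset.costs.dfs_annual_total,
            c_relapse_episode=pset.costs.relapse_episode_total,
            c_bc_death=pset.costs.bc_death.mean,
            p_incidental=pset.contraindications.incidental.distribution_mean,
            p_malignant=pset.contraindications.malignant_incidental.distribution_mean,
            contraindication_sum=pset.contraindications.prevalence_sum(),
            p_nsf=pset.contraindications.nsf.mean,
            p_ats=pset.contraindications.ats.mean,
            uptake_current=pset.uptake_current,
        )


def rescale_tps(tps, tau: float, tau_base: float) -> np.ndarray:
    """Counterfactual comparator tps under hazard ratio ``tau``.

    The comparator arm's printed yearly probabilities anchor the pathway: the
    guided-arm cumulative hazard is reconstructed as ``tau_base * H`` from
    them, so a different hazard ratio gives
    ``tp' = 1 - (1 - tp)**(tau_base/tau)``.  ``tau = tau_base`` reproduces
    the printed probabilities exactly; smaller ``tau`` (guided arm better)
    raises the comparator probabilities.
    """
    if tau <= 0:
        raise ValueError(f"hazard ratio must be positive, got {tau}")
    tps = np.asarray(tps, float)
    return 1.0 - (1.0 - tps) ** (tau_base / tau)


def sample_inputs(
    pset: ParameterSet,
    rng: np.random.Generator,
    n: int,
    hr_mode: str = "resample",
) -> list[ModelInputs]:
    """``n`` joint draws of all model parameters (one draw per PSA iteration).

    ``hr_mode="resample"`` samples the two hazard ratios and re-derives the
    conventional-arm transition probabilities from them via
    :func:`rescale_tps`; ``hr_mode="fixed"`` keeps the printed
    conventional-arm probabilities in every draw (they carry no distribution
    of their own).
    """
    if hr_mode not in ("resample", "fixed"):
        raise ValueError(f"unknown hr_mode {hr_mode!r}")
    if n < 1:
        raise ValueError("need at least one draw")
    base = ModelInputs.from_means(pset)
    t = pset.transitions

    mon = pset.monitoring.sample(rng, n)

    def s(p, size=n):
        return np.atleast_1d(p.sample(rng, size))

    tox_prob = {
        k: {b: s(p) for b, p in blocks.items()} for k, blocks in pset.toxicity.prob.items()
    }
    tox_util = {k: s(u) for k, u in pset.toxicity.utility.items()}
    tox_cost = {k: s(c) for k, c in pset.toxicity.cost.items()}
    relapse_false = np.column_stack([s(p) for p in t.relapse_false])
    bc_death_false = np.column_stack([s(p) for p in t.bc_death_false])
    hr_rfs = s(t.hr_rfs)
    hr_bcss = s(t.hr_bcss)
    u_chemo = s(pset.utilities.chemotherapy)
    u_dfs = s(pset.utilities.dfs)
    u_relapse = s(pset.utilities.relapse)
    u_anxiety = s(pset.utilities.anxiety)
    u_aml = s(pset.utilities.aml_mds)

    def cost_total(components):
        return np.sum(np.column_stack([s(p) for p in components.values()]), axis=1)

    c_6xac = cost_total(pset.costs.regimen_6xac)
    c_acdc = cost_total(pset.costs.regimen_acdc)
    c_mon = cost_total(pset.costs.monitoring)
    c_confirm = s(pset.costs.confirm_incidental)
    c_dfs = cost_total(pset.costs.dfs_annual)
    c_relapse = 0.5 * (cost_total(pset.costs.relapse_local) + cost_total(pset.costs.relapse_distant))
    c_death = s(pset.costs.bc_death)
    p_inc = s(pset.contraindications.incidental)
    p_mal = s(pset.contraindications.malignant_incidental)

    draws = []
    for i in range(n):
        if hr_mode == "resample":
            rc = rescale_tps(base.relapse_conventional, float(hr_rfs[i]), t.hr_rfs.mean)
            dc = rescale_tps(base.bc_death_conventional, float(hr_bcss[i]), t.hr_bcss.mean)
        else:
            rc = base.relapse_conventional
            dc = base.bc_death_conventional
        draws.append(
            replace(
                base,
                monitoring=mon[i],
                tox_prob={k: {b: float(v[i]) for b, v in blocks.items()} for k, blocks in tox_prob.items()},
                tox_util={k: float(v[i]) for k, v in tox_util.items()},
                tox_cost={k: float(v[i]) for k, v in tox_cost.items()},
                relapse_false=relapse_false[i],
                bc_death_false=bc_death_false[i],
                relapse_conventional=rc,
                bc_death_conventional=dc,
                hr_rfs=float(hr_rfs[i]),
                hr_bcss=float(hr_bcss[i]),
                u_chemo=float(u_chemo[i]),
                u_dfs=float(u_dfs[i]),
                u_relapse=float(u_relapse[i]),
                u_anxiety=float(u_anxiety[i]),
                u_aml=float(u_aml[i]),
                c_regimen_6xac=float(c_6xac[i]),
                c_regimen_acdc=float(c_acdc[i]),
                c_monitoring=float(c_mon[i]),
                c_confirm=float(c_confirm[i]),
                c_dfs_annual=float(c_dfs[i]),
                c_relapse_episode=float(c_relapse[i]),
                c_bc_death=float(c_death[i]),
                p_incidental=float(p_inc[i]),
                p_malignant=float(p_mal[i]),
            )
        )
    return draws


# ---------------------------------------------------------------------------
# arm specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subgroup:
    name: str
    weight: float
    regimen: str  # "6xAC" or "3xAC+3xDC"
    relapse_tps: np.ndarray
    bc_death_tps: np.ndarray
    monitored: bool


@dataclass(frozen=True)
class ArmSpec:
    """A treatment arm as a weighted mixture of response subgroups."""

    name: str
    subgroups: tuple[Subgroup, ...]
    bc_death_indexing: str = "since-relapse"  # or "model-time"

    def __post_init__(self):
        w = sum(g.weight for g in self.subgroups)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"subgroup weights must sum to 1, got {w}")
        if self.bc_death_indexing not in ("since-relapse", "model-time"):
            raise ValueError(f"unknown bc_death_indexing {self.bc_death_indexing!r}")


def rg_arm(inputs: ModelInputs, bc_death_indexing: str = "since-relapse") -> ArmSpec:
    """Response-guided arm: four monitored subgroups.

    Favourable responders (continuing the anthracycline regimen) receive
    6xAC; unfavourable responders switch to docetaxel/capecitabine
    (3xAC+3xDC).  Truly classified subgroups never relapse nor die of breast
    cancer; falsely classified subgroups follow the observed relapse and
    breast-cancer-death probabilities.
    """
    w = inputs.monitoring
    zeros = np.zeros_like(inputs.relapse_false)
    subgroups = (
        Subgroup("true_favourable", float(w[0]), "6xAC", zeros, zeros, True),
        Subgroup("true_unfavourable", float(w[1]), "3xAC+3xDC", zeros, zeros, True),
        Subgroup("false_favourable", float(w[2]), "6xAC", inputs.relapse_false, inputs.bc_death_false, True),
        Subgroup("false_unfavourable", float(w[3]), "3xAC+3xDC", inputs.relapse_false, inputs.bc_death_false, True),
    )
    return ArmSpec("RG-NACT", subgroups, bc_death_indexing)


def conventional_arm(inputs: ModelInputs, bc_death_indexing: str = "since-relapse") -> ArmSpec:
    """Conventional arm: unmonitored, 6xAC, printed transition probabilities."""
    sub = Subgroup(
        "conventional", 1.0, "6xAC", inputs.relapse_conventional,
        inputs.bc_death_conventional, False,
    )
    return ArmSpec("conventional-NACT", (sub,), bc_death_indexing)


# ---------------------------------------------------------------------------
# toxicity burden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToxicityEvent:
    name: str
    probability: float
    utility: float
    cost: float


def toxicity_burden(regimen: str, inputs: ModelInputs):
    """Year-1 toxicity events plus the year-5 AML/MDS probability.

    For the sequential 3xAC+3xDC path, vomiting and neutropenia occur in
    both blocks; their joint probability is the product of the per-block
    probabilities (independent events).  CHF and AML/MDS are
    anthracycline-dose dependent; hand-foot syndrome and desquamation occur
    only under docetaxel/capecitabine and carry no treatment cost.
    """
    p = inputs.tox_prob
    if regimen == "6xAC":
        probs = {
            "vomiting": p["vomiting"]["ac3"],
            "neutropenia": p["neutropenia"]["ac3"],
            "hfs": 0.0,
            "desquamation": 0.0,
            "chf": p["chf"]["ac6"],
        }
        p_aml = p["aml_mds"]["ac6"]
    elif regimen == "3xAC+3xDC":
        probs = {
            "vomiting": p["vomiting"]["ac3"] * p["vomiting"]["dc3"],
            "neutropenia": p["neutropenia"]["ac3"] * p["neutropenia"]["dc3"],
            "hfs": p["hfs"]["dc3"],
            "desquamation": p["desquamation"]["dc3"],
            "chf": p["chf"]["ac3"],
        }
        p_aml = p["aml_mds"]["ac3"]
    else:
        raise ValueError(f"unknown regimen {regimen!r}")
    events = tuple(
        ToxicityEvent(name, probs[name], inputs.tox_util[name], inputs.tox_cost[name])
        for name in YEAR1_TOXICITIES
    )
    return events, p_aml


def expected_year1_utility(events, u_chemo: float, p_anxiety: float = 0.0, u_anxiety: float = 1.0) -> float:
    """Expected year-1 utility under independent toxicity/anxiety occurrence.

    Patients with no event accrue the chemotherapy utility; patients with
    one or more events accrue the minimum of the utilities of the events
    they experience (an incidental-finding anxiety episode counts as an
    event with the anxiety utility).
    """
    items = [(e.probability, e.utility) for e in events if e.probability > 0]
    if p_anxiety > 0:
        items.append((p_anxiety, u_anxiety))
    # distribution of the running minimum utility; None = no event yet
    dist: dict[float | None, float] = {None: 1.0}
    for p, u in items:
        new: dict[float | None, float] = {}
        for cur, mass in dist.items():
            new[cur] = new.get(cur, 0.0) + mass * (1.0 - p)
            nxt = u if cur is None else min(cur, u)
            new[nxt] = new.get(nxt, 0.0) + mass * p
        dist = new
    return sum((u_chemo if cur is None else cur) * mass for cur, mass in dist.items())


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

@dataclass
class ArmOutcome:
    """Per-patient expected outcomes of one arm over the horizon."""

    ly: float = 0.0
    qaly: float = 0.0
    cost: float = 0.0
    ly_disc: float = 0.0
    qaly_disc: float = 0.0
    cost_disc: float = 0.0
    events: dict = field(default_factory=dict)

    def __add__(self, other):
        out = ArmOutcome(
            self.ly + other.ly, self.qaly + other.qaly, self.cost + other.cost,
            self.ly_disc + other.ly_disc, self.qaly_disc + other.qaly_disc,
            self.cost_disc + other.cost_disc,
        )
        keys = set(self.events) | set(other.events)
        out.events = {k: self.events.get(k, 0.0) + other.events.get(k, 0.0) for k in keys}
        return out

    def scaled(self, w: float) -> "ArmOutcome":
        return ArmOutcome(
            self.ly * w, self.qaly * w, self.cost * w,
            self.ly_disc * w, self.qaly_disc * w, self.cost_disc * w,
            {k: v * w for k, v in self.events.items()},
        )

    def blend(self, other: "ArmOutcome", w_self: float) -> "ArmOutcome":
        return self.scaled(w_self) + other.scaled(1.0 - w_self)


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle state occupancy and accruals for one arm."""

    frame: pd.DataFrame

    def to_csv(self, path):
        long = self.frame.melt(id_vars="cycle", var_name="state", value_name="value")
        long.to_csv(path, index=False)


def discounted_sum(stream, rate: float) -> float:
    """Present value of per-cycle amounts, cycle index starting at 1."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    stream = np.asarray(stream, float)
    t = np.arange(1, stream.size + 1)
    return float(np.sum(stream / (1.0 + rate) ** t))


# ---------------------------------------------------------------------------
# the cohort engine
# ---------------------------------------------------------------------------

def _run_subgroup(sub: Subgroup, inputs: ModelInputs, life_table: LifeTable,
                  horizon: int, indexing: str):
    events_y1, p_aml = toxicity_burden(sub.regimen, inputs)
    p_anx = inputs.p_incidental if sub.monitored else 0.0
    u_year1 = expected_year1_utility(events_y1, inputs.u_chemo, p_anx, inputs.u_anxiety)
    tox_cost_y1 = sum(e.probability * e.cost for e in events_y1)
    regimen_cost = inputs.c_regimen_6xac if sub.regimen == "6xAC" else inputs.c_regimen_acdc

    occ_dfs = 1.0
    occ_r = np.zeros(horizon)  # tunnel index j: (j+1) years since relapse
    dead_bc = 0.0
    dead_oc = 0.0

    ly = np.zeros(horizon)
    qaly = np.zeros(horizon)
    cost = np.zeros(horizon)
    rows = []
    relapses = 0.0
    bc_deaths = 0.0
    aml_events = 0.0

    for t in range(1, horizon + 1):
        q = life_table.q(START_AGE + t - 1)
        alive = occ_dfs + occ_r.sum()
        rows.append(
            {"cycle": t, "dfs": occ_dfs, "relapse": occ_r.sum(),
             **{f"relapse_y{j + 1}": occ_r[j] for j in range(horizon)},
             "death_bc": dead_bc, "death_other": dead_oc}
        )

        # --- accruals over cycle t -------------------------------------
        ly[t - 1] = alive
        u_dfs_t = u_year1 if t == 1 else inputs.u_dfs
        qaly_t = u_dfs_t * occ_dfs + inputs.u_relapse * occ_r.sum()
        cost_t = inputs.c_dfs_annual * occ_dfs
        if t == 1:
            cost_t += regimen_cost + tox_cost_y1
            if sub.monitored:
                cost_t += inputs.c_monitoring + inputs.p_incidental * inputs.c_confirm
        if t == AML_CYCLE and t <= horizon:
            # long-term AML/MDS: cost plus utility substitution for the
            # affected fraction of patients alive this cycle
            qaly_t = (1.0 - p_aml) * qaly_t + p_aml * alive * inputs.u_aml
            cost_t += p_aml * alive * inputs.tox_cost["aml_mds"]
            aml_events += p_aml * alive

        # --- end-of-cycle transitions -----------------------------------
        r_t = float(sub.relapse_tps[t - 1]) if t - 1 < len(sub.relapse_tps) else 0.0
        new_relapse = occ_dfs * (1.0 - q) * r_t
        dfs_dead_oc = occ_dfs * q
        r_dead_oc = occ_r.sum() * q

        if indexing == "since-relapse":
            m = np.array([
                float(sub.bc_death_tps[j]) if j < len(sub.bc_death_tps) else float(sub.bc_death_tps[-1])
                for j in range(horizon)
            ])
        else:  # model-time: this cycle's probability applies to all R occupants
            m_t = float(sub.bc_death_tps[t - 1]) if t - 1 < len(sub.bc_death_tps) else 0.0
            m = np.full(horizon, m_t)
        r_dead_bc = occ_r * (1.0 - q) * m
        survivors_r = occ_r * (1.0 - q) * (1.0 - m)

        new_r = np.zeros(horizon)
        new_r[0] = new_relapse
        new_r[1:] = survivors_r[:-1]
        new_r[-1] += survivors_r[-1]  # sojourns beyond the horizon pool in the last tunnel

        cost_t += new_relapse * inputs.c_relapse_episode + r_dead_bc.sum() * inputs.c_bc_death

        relapses += new_relapse
        bc_deaths += r_dead_bc.sum()
        dead_bc += r_dead_bc.sum()
        dead_oc += dfs_dead_oc + r_dead_oc
        occ_dfs = occ_dfs * (1.0 - q) * (1.0 - r_t)
        occ_r = new_r

        qaly[t - 1] = qaly_t
        cost[t - 1] = cost_t

    chf_events = next(e.probability for e in events_y1 if e.name == "chf")
    outcome_events = {
        "relapses": relapses,
        "bc_deaths": bc_deaths,
        "chf": chf_events,
        "aml_mds": aml_events,
        "incidental_findings": p_anx,
        "anxiety_episodes": p_anx,
        "toxicity_episodes": sum(e.probability for e in events_y1),
    }
    return ly, qaly, cost, pd.DataFrame(rows), outcome_events


def run_cohort(
    arm: ArmSpec,
    inputs: ModelInputs,
    life_table: LifeTable,
    horizon: int = 5,
    discount_cost: float = 0.04,
    discount_effect: float = 0.015,
) -> tuple[MarkovTrace, ArmOutcome]:
    """Run the cohort model for one arm and accrue (discounted) outcomes.

    Returns the weighted state-occupancy trace and the per-patient expected
    life-years, QALYs, costs (discounted at ``discount_cost`` for costs and
    ``discount_effect`` for effects) and event counts.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if discount_cost < 0 or discount_effect < 0:
        raise ValueError("discount rates must be >= 0")

    ly = np.zeros(horizon)
    qaly = np.zeros(horizon)
    cost = np.zeros(horizon)
    events: dict[str, float] = {}
    frames = []
    for sub in arm.subgroups:
        s_ly, s_qaly, s_cost, s_frame, s_events = _run_subgroup(
            sub, inputs, life_table, horizon, arm.bc_death_indexing
        )
        ly += sub.weight * s_ly
        qaly += sub.weight * s_qaly
        cost += sub.weight * s_cost
        for k, v in s_events.items():
            events[k] = events.get(k, 0.0) + sub.weight * v
        frames.append(s_frame.drop(columns="cycle") * sub.weight)

    trace_frame = sum(frames)
    trace_frame.insert(0, "cycle", np.arange(1, horizon + 1))
    outcome = ArmOutcome(
        ly=float(ly.sum()),
        qaly=float(qaly.sum()),
        cost=float(cost.sum()),
        ly_disc=discounted_sum(ly, discount_effect),
        qaly_disc=discounted_sum(qaly, discount_effect),
        cost_disc=discounted_sum(cost, discount_cost),
        events=events,
    )
    return MarkovTrace(trace_frame), outcome
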