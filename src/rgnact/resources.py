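"""Resource-modelling analysis: scans, scanner throughput, staffing, harms.

A static capacity calculus layered on the decision model: given an
implementation scenario it computes the number of MRI scans performed, the
patients scanned per scanner, the full-time-equivalent (fte) MRI
technologists and breast radiologists required (at country and hospital
level), and the health outcomes gained (relapses and breast-cancer deaths
prevented, from the cohort model) and lost (excluded patients, nephrogenic
systemic fibrosis, congestive heart failure, AML/MDS, anxiety from
incidental findings, malignant incidental findings, technologists with
acute transition symptoms).

Staffing arithmetic: one scanning procedure occupies a technologist for 1 h
and a radiologist for 6.8 min of reading; a fully workable year is 1408 h.
All quantities are homogeneous of degree 1 in the scan count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import ScenarioConfig, excluded_for_contraindications
from .markov import LifeTable, ModelInputs, conventional_arm, rg_arm, run_cohort
from .params import ParameterSet

__all__ = [
    "StaffingConstants",
    "ResourceReport",
    "ResourceModel",
    "scans_required",
    "patients_per_scanner",
    "fte_technologists",
    "fte_radiologists",
    "reading_time_sensitivity",
    "transition_delta",
    "uptake_sweep",
]


@dataclass(frozen=True)
class StaffingConstants:
    workable_hours_per_year: float = 1408.0
    technologist_hours_per_scan: float = 1.0
    radiologist_minutes_per_scan: float = 6.8
    radiologist_minutes_alternative: float = 15.0  # reading-time sensitivity

    def __post_init__(self):
        for f in ("workable_hours_per_year", "technologist_hours_per_scan",
                  "radiologist_minutes_per_scan", "radiologist_minutes_alternative"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# elementary calculus
# ---------------------------------------------------------------------------

def scans_required(scenario: ScenarioConfig, contraindication_sum: float) -> tuple[int, float]:
    """(reported, unrounded) number of MRI scans over the horizon (1 scan/patient).

    Candidates = uptake share of the target population; contraindicated
    candidates are excluded (whole patients, rounded down).  A configured
    national scan estimate (current scenario) overrides the computed count.
    """
    if scenario.current_scans is not None:
        return int(scenario.current_scans), float(scenario.current_scans)
    candidates = round(scenario.uptake * scenario.n_target)
    excluded = int(np.floor(excluded_for_contraindications(candidates, [contraindication_sum])))
    unrounded = scenario.uptake * scenario.n_target * (1.0 - contraindication_sum)
    return candidates - excluded, unrounded


def patients_per_scanner(scans: float, scanners: int) -> float:
    if scanners <= 0:
        raise ValueError("scanner count must be positive")
    return scans / scanners


def fte_technologists(scans: float, constants: StaffingConstants = StaffingConstants()) -> float:
    return scans * constants.technologist_hours_per_scan / constants.workable_hours_per_year


def fte_radiologists(scans: float, constants: StaffingConstants = StaffingConstants(),
                     minutes: float | None = None) -> float:
    m = constants.radiologist_minutes_per_scan if minutes is None else minutes
    if m <= 0:
        raise ValueError("reading time must be positive")
    return scans * (m / 60.0) / constants.workable_hours_per_year


def reading_time_sensitivity(scans: float, minutes_grid=(6.8, 15.0),
                             constants: StaffingConstants = StaffingConstants()) -> pd.DataFrame:
    """Radiologist fte over a reading-time grid, with % change vs the first value."""
    minutes_grid = [float(m) for m in minutes_grid]
    if any(m <= 0 for m in minutes_grid):
        raise ValueError("reading times must be positive")
    base = minutes_grid[0]
    rows = [
        {
            "minutes_per_scan": m,
            "fte_radiologists": fte_radiologists(scans, constants, minutes=m),
            "percent_change": (m / base - 1.0) * 100.0,
        }
        for m in minutes_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the report
# ---------------------------------------------------------------------------

_COUNT_FIELDS = (
    "scans", "excluded_patients", "incidental_confirmations", "anxiety_episodes",
    "malignant_incidental", "chf", "aml_mds", "relapses_prevented",
    "bc_deaths_prevented", "patients_per_scanner", "scans_per_hospital",
    "patients_per_scanner_per_hospital", "nsf",
)
_FTE_FIELDS = (
    "fte_technologists", "fte_radiologists", "fte_technologists_per_hospital",
    "fte_radiologists_per_hospital", "ats_fte",
)


@dataclass(frozen=True)
class ResourceReport:
    """Unrounded resource quantities for one scenario (per 5-year horizon)."""

    scenario: str
    hospitals: int
    scanners: int
    scans: float
    excluded_patients: float
    patients_per_scanner: float
    fte_technologists: float
    fte_radiologists: float
    incidental_confirmations: float
    scans_per_hospital: float
    patients_per_scanner_per_hospital: float
    fte_technologists_per_hospital: float
    fte_radiologists_per_hospital: float
    relapses_prevented: float
    bc_deaths_prevented: float
    nsf: float
    ats_fte: float
    chf: float
    aml_mds: float
    anxiety_episodes: float
    malignant_incidental: float

    def rounded(self) -> dict:
        """Report-style values: counts to whole numbers, fte to 1-3 significant decimals."""
        out = {"scenario": self.scenario, "hospitals": self.hospitals, "scanners": self.scanners}
        for f in _COUNT_FIELDS:
            v = getattr(self, f)
            out[f] = int(round(v)) if v >= 0.5 else round(v, 2)
        for f in _FTE_FIELDS:
            v = getattr(self, f)
            if v >= 0.095:
                out[f] = round(v, 1)
            elif v >= 0.0095:
                out[f] = round(v, 2)
            else:
                out[f] = round(v, 3)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quantity": k, "value": v} for k, v in self.rounded().items()]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def transition_delta(current: ResourceReport, full: ResourceReport) -> pd.DataFrame:
    """Componentwise change (and % change on the current base) between scenarios."""
    rows = []
    for f in _COUNT_FIELDS + _FTE_FIELDS:
        cur, new = getattr(current, f), getattr(full, f)
        delta = new - cur
        pct = (delta / cur * 100.0) if cur != 0 else np.nan
        rows.append({"quantity": f, "current": cur, "full": new,
                     "delta": delta, "percent_change": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ResourceModel:
    """Resource requirements and health outcomes of one implementation scenario.

    ``fit()`` returns a :class:`ResourceReport`; health outcomes marked
    "derived from the cohort model" (relapses/deaths prevented, CHF, AML/MDS)
    come from the same Markov engine as the cost-effectiveness analysis.
    """

    def __init__(
        self,
        params: ParameterSet,
        scenario: ScenarioConfig,
        life_table: LifeTable | None = None,
        constants: StaffingConstants = StaffingConstants(),
        read_minutes: float | None = None,
        bc_death_indexing: str = "since-relapse",
        horizon: int = 5,
    ):
        if life_table is None:
            from .synthetic import synthetic_life_table

            life_table = synthetic_life_table()
        self.params = params
        self.scenario = scenario
        self.life_table = life_table
        self.constants = constants
        self.read_minutes = read_minutes
        self.bc_death_indexing = bc_death_indexing
        self.horizon = horizon

    def fit(self) -> ResourceReport:
        inputs = ModelInputs.from_means(self.params)
        sc = self.scenario
        contra = inputs.contraindication_sum
        scans, scans_unrounded = scans_required(sc, contra)
        candidates = round(sc.uptake * sc.n_target)
        excluded = float(np.floor(excluded_for_contraindications(candidates, [contra])))

        pps = patients_per_scanner(scans, sc.scanners)
        tech = fte_technologists(scans, self.constants)
        rad = fte_radiologists(scans, self.constants, minutes=self.read_minutes)
        scans_hosp = scans / sc.hospitals
        scanners_per_hosp = sc.scanners / sc.hospitals
        pps_hosp = scans_hosp / scanners_per_hosp
        tech_hosp = fte_technologists(scans_hosp, self.constants)
        rad_hosp = fte_radiologists(scans_hosp, self.constants, minutes=self.read_minutes)

        incidental = scans * inputs.p_incidental
        kw = dict(life_table=self.life_table, horizon=self.horizon)
        _, rg = run_cohort(rg_arm(inputs, self.bc_death_indexing), inputs, **kw)
        _, conv = run_cohort(conventional_arm(inputs, self.bc_death_indexing), inputs, **kw)
        n_rg = float(scans)  # one scan per guided patient
        n_conv = sc.n_target - n_rg

        return ResourceReport(
            scenario=sc.name,
            hospitals=sc.hospitals,
            scanners=sc.scanners,
            scans=float(scans),
            excluded_patients=excluded,
            patients_per_scanner=pps,
            fte_technologists=tech,
            fte_radiologists=rad,
            incidental_confirmations=incidental,
            scans_per_hospital=scans_hosp,
            patients_per_scanner_per_hospital=pps_hosp,
            fte_technologists_per_hospital=tech_hosp,
            fte_radiologists_per_hospital=rad_hosp,
            relapses_prevented=n_rg * (conv.events["relapses"] - rg.events["relapses"]),
            bc_deaths_prevented=n_rg * (conv.events["bc_deaths"] - rg.events["bc_deaths"]),
            nsf=float(scans) * inputs.p_nsf,
            ats_fte=tech * inputs.p_ats,
            chf=n_rg * rg.events["chf"] + n_conv * conv.events["chf"],
            aml_mds=n_rg * rg.events["aml_mds"] + n_conv * conv.events["aml_mds"],
            anxiety_episodes=incidental,
            malignant_incidental=incidental * inputs.p_malignant,
        )


def uptake_sweep(
    params: ParameterSet,
    uptakes=(0.2, 0.4, 0.6, 0.8),
    life_table: LifeTable | None = None,
    n_target: int = 6306,
    **kwargs,
) -> pd.DataFrame:
    """Resource quantities across implementation rates (unrounded)."""
    rows = []
    for u in uptakes:
        report = ResourceModel(
            params, ScenarioConfig.with_uptake(u, n_target), life_table, **kwargs
        ).fit()
        rows.append({"uptake": u, **report.to_dict()})
    return pd.DataFrame(rows).drop(columns=["scenario"])
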