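"""Synthetic stand-ins for inputs the underlying studies do not publish.

Three generators:

* individual patient relapse/death times whose yearly event probabilities
  match a given transition-probability vector (piecewise exponential with a
  constant hazard within each 1-year interval) -- emulates the unpublished
  trial IPD behind the survival curves;
* a synthetic life table for women aged 50-55 (all-cause, non-breast-cancer
  mortality) -- stands in for national life tables, with a base rate and
  geometric age growth of the right order of magnitude for this population;
* the bundled base-case parameter fixture.

All outputs are labelled synthetic; users can substitute real CSV inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import START_AGE, LifeTable
from .params import ParameterSet, default_parameter_path, load_parameters

__all__ = [
    "SyntheticIPDConfig",
    "generate_ipd",
    "synthetic_life_table",
    "fixture_parameter_set",
]

_MAX_HAZARD = -np.log(1e-15)  # tp = 1 -> event (numerically) certain within the year


@dataclass(frozen=True)
class SyntheticIPDConfig:
    """Configuration for piecewise-exponential event-time generation."""

    tps: tuple[float, ...]  # yearly event probabilities tp1..tpH
    n: int = 1000
    censor_prob: float = 0.0  # independent per-year censoring probability
    seed: int = 0
    group: str = "synthetic"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not self.tps:
            raise ValueError("at least one yearly tp is required")
        for tp in self.tps:
            if not 0.0 <= tp <= 1.0:
                raise ValueError(f"tp {tp} outside [0, 1]")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ValueError("censor_prob must lie in [0, 1)")


def _piecewise_exponential_times(rates: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Event times under yearly-constant hazards; inf = no event within horizon."""
    horizon = rates.size
    cum = np.concatenate([[0.0], np.cumsum(rates)])
    target = rng.exponential(size=n)
    times = np.full(n, np.inf)
    for k in range(horizon):
        lam = rates[k]
        in_year = (target >= cum[k]) & (target < cum[k + 1]) & np.isinf(times)
        if lam > 0:
            times[in_year] = k + (target[in_year] - cum[k]) / lam
    return times


def generate_ipd(config: SyntheticIPDConfig) -> pd.DataFrame:
    """Synthetic IPD whose yearly event fractions converge to ``config.tps``.

    Event times are piecewise exponential with yearly rate
    ``lambda_t = -ln(1 - tp_t)``; subjects event-free (and uncensored) at the
    horizon are censored there.  Runs are reproducible by seed.
    """
    rng = np.random.default_rng(config.seed)
    rates = np.array([min(-np.log1p(-tp), _MAX_HAZARD) if tp < 1 else _MAX_HAZARD
                      for tp in config.tps])
    horizon = float(rates.size)
    t_event = _piecewise_exponential_times(rates, config.n, rng)
    if config.censor_prob > 0:
        c_rate = -np.log1p(-config.censor_prob)
        t_censor = _piecewise_exponential_times(
            np.full(rates.size, c_rate), config.n, rng
        )
    else:
        t_censor = np.full(config.n, np.inf)

    observed = np.minimum(np.minimum(t_event, t_censor), horizon)
    event = (t_event <= t_censor) & (t_event <= horizon)
    observed = np.maximum(observed, 1e-9)  # follow-up strictly positive
    return pd.DataFrame({
        "time_years": observed,
        "event": event.astype(int),
        "group": config.group,
    })


def synthetic_life_table(
    base: float = 0.0025,
    growth: float = 1.1,
    ages=range(START_AGE, START_AGE + 6),
) -> LifeTable:
    """Synthetic all-cause mortality table, ``q(age) = base * growth**(age-50)``.

    Defaults (base 0.0025, growth 1.1 per year of age) give the order of
    magnitude of female all-cause mortality at ages 50-55; values are
    clamped to [0, 1].  This is a synthetic stand-in for a national life
    table -- supply a real ``age, annual_mortality`` CSV for actual use.
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError(f"base mortality must lie in [0, 1], got {base}")
    if growth < 1.0:
        raise ValueError(f"growth factor must be >= 1, got {growth}")
    ages = np.asarray(list(ages), float)
    q = np.clip(base * growth ** (ages - START_AGE), 0.0, 1.0)
    return LifeTable(ages=ages, mortality=q)


def fixture_parameter_set() -> ParameterSet:
    """The complete bundled base-case parameterisation."""
    return load_parameters(default_parameter_path())
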