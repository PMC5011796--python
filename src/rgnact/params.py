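"""Model input parameters and their sampling distributions.

Every quantity that enters the decision model -- monitoring performance,
toxicity probabilities, transition probabilities, hazard ratios, utilities,
unit costs and screening prevalences -- is represented as an
:class:`UncertainParam`: a point estimate (used in the deterministic base
case) together with a second-order distribution used by the probabilistic
sensitivity analysis (PSA).

Distribution conventions follow standard health-economics practice:

* binomial quantities (toxicity and transition probabilities, utilities
  reported with event counts) carry a beta distribution parameterised by the
  counts ``alpha``/``beta``;
* costs carry a gamma distribution moment-matched from mean and standard
  error (shape ``(mean/se)**2``, scale ``se**2/mean``);
* the four monitoring-performance proportions are sampled jointly from a
  Dirichlet distribution so that every draw lies on the simplex;
* hazard ratios are sampled from a (possibly truncated) normal distribution
  on (0, inf);
* parameters without a reported standard error default to ``se = 0.25*mean``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "UncertainParam",
    "MonitoringPerformance",
    "ToxicityTable",
    "TransitionTable",
    "UtilitySet",
    "CostSet",
    "ContraindicationSet",
    "ParameterSet",
    "ParameterError",
    "beta_from_counts",
    "gamma_from_mean_se",
    "dirichlet_from_proportions",
    "load_parameters",
    "save_parameters",
    "default_parameter_path",
]

DEFAULT_SE_FRACTION = 0.25  # se assumed as 0.25*mean when not reported

_FAMILIES = {"beta", "gamma", "dirichlet-component", "normal", "truncated-normal", "fixed"}


class ParameterError(ValueError):
    """Raised when a configuration value violates a parameter invariant."""


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def beta_from_counts(alpha: float, beta: float):
    """Beta sampler parameterised by pseudo-counts, mean ``alpha/(alpha+beta)``.

    Returns a frozen scipy distribution.  Used for binomial model inputs
    where the source reports events and complements.
    """
    if alpha < 0 or beta < 0:
        raise ParameterError(f"beta counts must be non-negative, got {alpha}/{beta}")
    if alpha + beta <= 0:
        raise ParameterError("beta counts must not both be zero")
    return stats.beta(alpha, beta)


def gamma_from_mean_se(mean: float, se: float):
    """Gamma sampler moment-matched to ``mean``/``se``.

    shape = (mean/se)^2, scale = se^2/mean, so the sampler has exactly the
    requested first two moments.
    """
    if mean <= 0:
        raise ParameterError(f"gamma mean must be positive, got {mean}")
    if se <= 0:
        raise ParameterError(f"gamma se must be positive, got {se}")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return stats.gamma(shape, scale=scale)


class _DirichletSampler:
    """Dirichlet over the non-degenerate components; zero-mean components stay 0."""

    def __init__(self, alpha: np.ndarray):
        self.alpha = alpha
        self._support = alpha > 0
        self._inner = stats.dirichlet(alpha[self._support])

    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def rvs(self, size: int = 1, random_state=None) -> np.ndarray:
        out = np.zeros((size, self.alpha.size))
        out[:, self._support] = self._inner.rvs(size=size, random_state=random_state)
        return out


def dirichlet_from_proportions(means: Sequence[float], concentration: float) -> _DirichletSampler:
    """Dirichlet sampler with componentwise means proportional to ``means``.

    ``concentration`` is the total pseudo-count; every draw sums to one.
    Components with zero mean are degenerate at zero.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means < 0):
        raise ParameterError("dirichlet means must be non-negative")
    total = means.sum()
    if total <= 0:
        raise ParameterError("dirichlet means must not all be zero")
    if concentration <= 0:
        raise ParameterError("dirichlet concentration must be positive")
    return _DirichletSampler(concentration * means / total)


# ---------------------------------------------------------------------------
# UncertainParam
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertainParam:
    """A model input: point estimate plus PSA distribution.

    ``mean`` is the deterministic (base-case) value.  For the beta family the
    distribution mean ``alpha/(alpha+beta)`` may differ from the printed point
    estimate in the last digit; :attr:`distribution_mean` exposes the former.
    """

    mean: float
    family: str = "fixed"
    se: float | None = None
    alpha: float | None = None
    beta: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ParameterError(f"{self.name or 'parameter'}: unknown family {self.family!r}")
        if self.se is not None and self.se < 0:
            raise ParameterError(f"{self.name}: se must be >= 0")
        if self.family == "beta":
            if self.alpha is None or self.beta is None:
                raise ParameterError(f"{self.name}: beta family requires both counts")
            m = self.alpha / (self.alpha + self.beta)
            if not 0.0 <= m <= 1.0:
                raise ParameterError(f"{self.name}: beta mean outside [0,1]")
        if self.family == "gamma" and self.mean <= 0:
            raise ParameterError(f"{self.name}: gamma family requires mean > 0")

    # -- derived quantities -------------------------------------------------
    @property
    def effective_se(self) -> float:
        """Reported SE, or the ``0.25*mean`` fallback."""
        if self.se is not None and self.se > 0:
            return self.se
        return DEFAULT_SE_FRACTION * abs(self.mean)

    @property
    def distribution_mean(self) -> float:
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta)
        return self.mean

    def frozen(self):
        """The frozen scipy distribution backing :meth:`sample` (None if fixed)."""
        if self.family == "fixed":
            return None
        if self.family == "beta":
            return beta_from_counts(self.alpha, self.beta)
        if self.family == "gamma":
            return gamma_from_mean_se(self.mean, self.effective_se)
        if self.family == "normal":
            return stats.norm(self.mean, self.effective_se)
        if self.family == "truncated-normal":
            # support (0, inf): hazard ratios must stay positive
            se = self.effective_se
            return stats.truncnorm((0.0 - self.mean) / se, np.inf, loc=self.mean, scale=se)
        raise ParameterError(f"{self.name}: family {self.family} has no marginal sampler")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the PSA distribution (degenerate at ``mean`` if fixed)."""
        if self.family == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        draws = self.frozen().rvs(size=size if size is not None else 1, random_state=rng)
        if self.family == "normal":
            # normal-family hazard ratios must remain positive
            draws = np.clip(draws, 1e-9, None)
        return draws if size is not None else float(draws[0])

    @classmethod
    def from_config(cls, node, name: str = "", family: str | None = None) -> "UncertainParam":
        """Build from a YAML/JSON node: scalar, or mapping with mean/se/alpha/beta/ess."""
        if isinstance(node, (int, float)):
            return cls(mean=float(node), family="fixed", name=name)
        if not isinstance(node, Mapping):
            raise ParameterError(f"{name}: expected scalar or mapping, got {type(node).__name__}")
        mean = node.get("mean")
        alpha = node.get("alpha")
        beta = node.get("beta")
        se = node.get("se")
        ess = node.get("ess")  # effective sample size for moment-matched betas
        if family is None:
            family = node.get("family")
        if alpha is not None and beta is None and ess is None:
            raise ParameterError(f"{name}: alpha given without beta")
        if ess is not None and mean is not None:
            # beta from mean and effective sample size
            alpha, beta = float(mean) * float(ess), (1.0 - float(mean)) * float(ess)
        if family is None:
            family = "beta" if alpha is not None else "fixed"
        if mean is None:
            if family == "beta" and alpha is not None:
                mean = alpha / (alpha + beta)
            else:
                raise ParameterError(f"{name}: mean missing")
        if family == "beta" and alpha is None:
            # moment-match a beta when only mean/se are known
            m = float(mean)
            s = float(se) if se else DEFAULT_SE_FRACTION * m
            if not 0 < m < 1:
                raise ParameterError(f"{name}: beta moment-matching requires mean in (0,1)")
            nu = m * (1 - m) / s**2 - 1.0
            if nu <= 0:
                raise ParameterError(f"{name}: se too large for a beta distribution")
            alpha, beta = m * nu, (1 - m) * nu
        return cls(
            mean=float(mean),
            family=family,
            se=None if se is None else float(se),
            alpha=None if alpha is None else float(alpha),
            beta=None if beta is None else float(beta),
            name=name,
        )

    def to_config(self) -> dict | float:
        if self.family == "fixed" and self.se is None:
            return self.mean
        out = {"mean": self.mean, "family": self.family}
        if self.se is not None:
            out["se"] = self.se
        if self.alpha is not None:
            out["alpha"] = self.alpha
        if self.beta is not None:
            out["beta"] = self.beta
        return out


def _check_probability(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} = {value} outside [0, 1]")
    return float(value)


# ---------------------------------------------------------------------------
# grouped parameter containers
# ---------------------------------------------------------------------------

SUBGROUPS = ("true_favourable", "true_unfavourable", "false_favourable", "false_unfavourable")


@dataclass(frozen=True)
class MonitoringPerformance:
    """Proportions of true/false favourable/unfavourable MRI response calls.

    The raw proportions are renormalised to the simplex at load time (the
    source means sum to 1.01).  ``concentration`` is the Dirichlet total
    pseudo-count, moment-matched on the first component's standard error.
    """

    raw_means: tuple[float, float, float, float]
    ses: tuple[float, float, float, float]

    @property
    def means(self) -> np.ndarray:
        raw = np.asarray(self.raw_means, dtype=float)
        return raw / raw.sum()

    @property
    def concentration(self) -> float:
        p1 = self.means[0]
        return p1 * (1.0 - p1) / self.ses[0] ** 2 - 1.0

    @property
    def p_true_fav(self) -> float:
        return float(self.means[0])

    @property
    def p_true_unfav(self) -> float:
        return float(self.means[1])

    @property
    def p_false_fav(self) -> float:
        return float(self.means[2])

    @property
    def p_false_unfav(self) -> float:
        return float(self.means[3])

    def sampler(self):
        return dirichlet_from_proportions(self.means, self.concentration)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.sampler().rvs(size=size, random_state=rng)

    def validate(self):
        for v, s in zip(self.raw_means, self.ses):
            _check_probability(v, "monitoring proportion")
            if s <= 0:
                raise ParameterError("monitoring SEs must be positive")
        if not math.isclose(float(self.means.sum()), 1.0, abs_tol=1e-12):
            raise ParameterError("normalised monitoring proportions must sum to 1")


REGIMENS = ("6xAC", "3xAC+3xDC")
TOXICITIES = ("vomiting", "hfs", "neutropenia", "desquamation", "chf", "aml_mds")
ZERO_COST_TOXICITIES = frozenset({"hfs", "desquamation"})  # no curative treatment


@dataclass(frozen=True)
class ToxicityTable:
    """Per-regimen toxicity probabilities with utilities and episode costs.

    Probabilities are stored per 3-course block (3xAC / 3xDC) plus explicit
    dose-dependent entries for 6xAC (CHF, AML/MDS).  Hand-foot syndrome and
    desquamation carry zero treatment cost.
    """

    prob: Mapping[str, Mapping[str, UncertainParam]]  # toxicity -> block -> p
    utility: Mapping[str, UncertainParam]
    cost: Mapping[str, UncertainParam]

    def validate(self):
        for tox, blocks in self.prob.items():
            for block, p in blocks.items():
                _check_probability(p.mean, f"p({tox}|{block})")
        for tox in ZERO_COST_TOXICITIES:
            if tox in self.cost and self.cost[tox].mean != 0:
                raise ParameterError(f"{tox} must be exempt of costs")
        for tox, u in self.utility.items():
            _check_probability(u.mean, f"utility({tox})")


@dataclass(frozen=True)
class TransitionTable:
    """Yearly relapse and breast-cancer-death transition probabilities.

    ``relapse_false`` applies to the falsely-classified response-guided
    subgroups; the truly-classified subgroups have zero relapse and
    breast-cancer-death probability at all times.  Conventional-arm values
    are the printed base case; the hazard-ratio pathway rescales them in
    sensitivity/probabilistic analyses.
    """

    relapse_false: tuple[UncertainParam, ...]
    relapse_conventional: tuple[UncertainParam, ...]
    bc_death_false: tuple[UncertainParam, ...]
    bc_death_conventional: tuple[UncertainParam, ...]
    hr_rfs: UncertainParam
    hr_bcss: UncertainParam

    def validate(self):
        for seq, label in (
            (self.relapse_false, "relapse_false"),
            (self.relapse_conventional, "relapse_conventional"),
            (self.bc_death_false, "bc_death_false"),
            (self.bc_death_conventional, "bc_death_conventional"),
        ):
            if len(seq) != 5:
                raise ParameterError(f"{label}: expected 5 yearly tps, got {len(seq)}")
            for i, p in enumerate(seq, 1):
                _check_probability(p.mean, f"{label}[{i}]")
        if self.hr_rfs.mean <= 0 or self.hr_bcss.mean <= 0:
            raise ParameterError("hazard ratios must be positive")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (EQ-5D scale, one value per model year)."""

    chemotherapy: UncertainParam
    dfs: UncertainParam
    relapse: UncertainParam
    anxiety: UncertainParam
    aml_mds: UncertainParam

    def validate(self):
        for f in dataclasses.fields(self):
            _check_probability(getattr(self, f.name).mean, f"utility {f.name}")


@dataclass(frozen=True)
class CostSet:
    """Unit costs (2013 Euros).

    Regimen, follow-up and relapse costs are stored per component so the PSA
    can sample each with its own gamma; totals are the component-mean sums.
    """

    regimen_6xac: Mapping[str, UncertainParam]
    regimen_acdc: Mapping[str, UncertainParam]
    monitoring: Mapping[str, UncertainParam]
    confirm_incidental: UncertainParam
    dfs_annual: Mapping[str, UncertainParam]
    relapse_local: Mapping[str, UncertainParam]
    relapse_distant: Mapping[str, UncertainParam]
    bc_death: UncertainParam

    @staticmethod
    def _total(components: Mapping[str, UncertainParam]) -> float:
        return float(sum(p.mean for p in components.values()))

    @property
    def regimen_6xac_total(self) -> float:
        return self._total(self.regimen_6xac)

    @property
    def regimen_acdc_total(self) -> float:
        return self._total(self.regimen_acdc)

    @property
    def monitoring_total(self) -> float:
        return self._total(self.monitoring)

    @property
    def dfs_annual_total(self) -> float:
        return self._total(self.dfs_annual)

    @property
    def relapse_episode_total(self) -> float:
        # detection+treatment cost averaged over local and distant relapse
        return 0.5 * (self._total(self.relapse_local) + self._total(self.relapse_distant))

    def validate(self):
        def _walk(node, label):
            if isinstance(node, Mapping):
                for k, v in node.items():
                    _walk(v, f"{label}.{k}")
            else:
                if node.mean < 0:
                    raise ParameterError(f"cost {label} must be >= 0")

        for f in dataclasses.fields(self):
            _walk(getattr(self, f.name), f.name)


@dataclass(frozen=True)
class ContraindicationSet:
    """MRI contraindication prevalences and scan-related event probabilities."""

    renal: UncertainParam
    gadolinium_allergy: UncertainParam
    ferrous_parts: UncertainParam
    claustrophobia: UncertainParam
    nsf: UncertainParam
    incidental: UncertainParam
    malignant_incidental: UncertainParam
    ats: UncertainParam
    # components entering the additive exclusion rule; the gadolinium-allergy
    # row quantifies NSF risk at scan time rather than an a-priori exclusion
    exclusion_components: tuple[str, ...] = ("renal", "ferrous_parts", "claustrophobia")

    def prevalence_sum(self) -> float:
        return float(sum(getattr(self, c).mean for c in self.exclusion_components))

    def validate(self):
        for f in dataclasses.fields(self):
            if f.name == "exclusion_components":
                continue
            _check_probability(getattr(self, f.name).mean, f"contraindication {f.name}")
        for c in self.exclusion_components:
            if not hasattr(self, c):
                raise ParameterError(f"unknown exclusion component {c!r}")
        if self.prevalence_sum() > 1.0:
            raise ParameterError("contraindication prevalences sum above 1")


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    monitoring: MonitoringPerformance
    toxicity: ToxicityTable
    transitions: TransitionTable
    utilities: UtilitySet
    costs: CostSet
    contraindications: ContraindicationSet
    uptake_current: float = 0.042

    def validate(self) -> "ParameterSet":
        self.monitoring.validate()
        self.toxicity.validate()
        self.transitions.validate()
        self.utilities.validate()
        self.costs.validate()
        self.contraindications.validate()
        _check_probability(self.uptake_current, "uptake")
        return self

    # -- iteration over every uncertain scalar (used by PSA and run logs) ---
    def iter_params(self):
        """Yield ``(path, UncertainParam)`` for every scalar parameter."""

        def _walk(node, path):
            if isinstance(node, UncertainParam):
                yield path, node
            elif isinstance(node, Mapping):
                for k, v in node.items():
                    yield from _walk(v, f"{path}.{k}")
            elif isinstance(node, tuple) and node and isinstance(node[0], UncertainParam):
                for i, v in enumerate(node, 1):
                    yield from _walk(v, f"{path}[{i}]")

        for group in ("toxicity", "transitions", "utilities", "costs", "contraindications"):
            container = getattr(self, group)
            for f in dataclasses.fields(container):
                yield from _walk(getattr(container, f.name), f"{group}.{f.name}")


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def default_parameter_path():
    """Path-like handle on the bundled base-case configuration."""
    return resources.files("rgnact.data") / "dutch_base_case.yaml"


_REQUIRED_TOP = (
    "monitoring", "toxicity", "transitions", "utilities", "costs", "screening",
)


def _param_map(node: Mapping, name: str, family: str | None = None):
    return {k: UncertainParam.from_config(v, f"{name}.{k}", family) for k, v in node.items()}


def load_parameters(source) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from YAML/JSON.

    ``source`` may be a path, an open file, a YAML string, or an
    already-parsed mapping.  Missing standard errors are filled by the
    ``0.25*mean`` rule at sampling time; every invariant is checked.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        elif hasattr(source, "read_text"):
            text = source.read_text()
        else:
            src = str(source)
            if "\n" in src:  # inline YAML document
                text = src
            else:
                with open(src) as fh:
                    text = fh.read()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ParameterError("configuration document must be a mapping")
    missing = [k for k in _REQUIRED_TOP if k not in doc]
    if missing:
        raise ParameterError(f"configuration missing keys: {missing}")

    mon = doc["monitoring"]
    try:
        raw = tuple(float(mon[g]["mean"]) for g in SUBGROUPS)
        ses = tuple(float(mon[g]["se"]) for g in SUBGROUPS)
    except KeyError as exc:
        raise ParameterError(f"monitoring block missing {exc}") from exc
    monitoring = MonitoringPerformance(raw_means=raw, ses=ses)

    tox = doc["toxicity"]
    prob = {
        t: _param_map(blocks, f"toxicity.prob.{t}", family=None)
        for t, blocks in tox["probabilities"].items()
    }
    toxicity = ToxicityTable(
        prob=prob,
        utility=_param_map(tox["utilities"], "toxicity.utility"),
        cost=_param_map(tox["costs"], "toxicity.cost", family=None),
    )

    tr = doc["transitions"]

    def _tp_seq(node, name):
        return tuple(UncertainParam.from_config(v, f"{name}[{i}]") for i, v in enumerate(node, 1))

    transitions = TransitionTable(
        relapse_false=_tp_seq(tr["relapse_false"], "relapse_false"),
        relapse_conventional=_tp_seq(tr["relapse_conventional"], "relapse_conventional"),
        bc_death_false=_tp_seq(tr["bc_death_false"], "bc_death_false"),
        bc_death_conventional=_tp_seq(tr["bc_death_conventional"], "bc_death_conventional"),
        hr_rfs=UncertainParam.from_config(tr["hr_rfs"], "hr_rfs", family="truncated-normal"),
        hr_bcss=UncertainParam.from_config(tr["hr_bcss"], "hr_bcss", family="normal"),
    )

    util = _param_map(doc["utilities"], "utilities")
    utilities = UtilitySet(
        chemotherapy=util["chemotherapy"],
        dfs=util["dfs"],
        relapse=util["relapse"],
        anxiety=util["anxiety"],
        aml_mds=util["aml_mds"],
    )

    c = doc["costs"]
    costs = CostSet(
        regimen_6xac=_param_map(c["regimen_6xac"], "costs.regimen_6xac", "gamma"),
        regimen_acdc=_param_map(c["regimen_acdc"], "costs.regimen_acdc", "gamma"),
        monitoring=_param_map(c["monitoring"], "costs.monitoring", "gamma"),
        confirm_incidental=UncertainParam.from_config(
            c["confirm_incidental"], "costs.confirm_incidental", "gamma"
        ),
        dfs_annual=_param_map(c["dfs_annual"], "costs.dfs_annual", "gamma"),
        relapse_local=_param_map(c["relapse_local"], "costs.relapse_local", "gamma"),
        relapse_distant=_param_map(c["relapse_distant"], "costs.relapse_distant", "gamma"),
        bc_death=UncertainParam.from_config(c["bc_death"], "costs.bc_death", "gamma"),
    )

    s = doc["screening"]
    contraindications = ContraindicationSet(
        renal=UncertainParam.from_config(s["renal"], "screening.renal"),
        gadolinium_allergy=UncertainParam.from_config(s["gadolinium_allergy"], "screening.gadolinium_allergy"),
        ferrous_parts=UncertainParam.from_config(s["ferrous_parts"], "screening.ferrous_parts"),
        claustrophobia=UncertainParam.from_config(s["claustrophobia"], "screening.claustrophobia"),
        nsf=UncertainParam.from_config(s["nsf"], "screening.nsf"),
        incidental=UncertainParam.from_config(s["incidental"], "screening.incidental"),
        malignant_incidental=UncertainParam.from_config(s["malignant_incidental"], "screening.malignant_incidental"),
        ats=UncertainParam.from_config(s["ats"], "screening.ats"),
        exclusion_components=tuple(s.get("exclusion_components", ("renal", "ferrous_parts", "claustrophobia"))),
    )

    pset = ParameterSet(
        monitoring=monitoring,
        toxicity=toxicity,
        transitions=transitions,
        utilities=utilities,
        costs=costs,
        contraindications=contraindications,
        uptake_current=float(doc.get("uptake_current", 0.042)),
    )
    return pset.validate()


def save_parameters(pset: ParameterSet, path) -> None:
    """Write a configuration document that round-trips through ``load_parameters``."""

    def _dump_map(m):
        return {k: v.to_config() for k, v in m.items()}

    doc = {
        "monitoring": {
            g: {"mean": m, "se": s}
            for g, m, s in zip(SUBGROUPS, pset.monitoring.raw_means, pset.monitoring.ses)
        },
        "toxicity": {
            "probabilities": {t: _dump_map(b) for t, b in pset.toxicity.prob.items()},
            "utilities": _dump_map(pset.toxicity.utility),
            "costs": _dump_map(pset.toxicity.cost),
        },
        "transitions": {
            "relapse_false": [p.to_config() for p in pset.transitions.relapse_false],
            "relapse_conventional": [p.to_config() for p in pset.transitions.relapse_conventional],
            "bc_death_false": [p.to_config() for p in pset.transitions.bc_death_false],
            "bc_death_conventional": [p.to_config() for p in pset.transitions.bc_death_conventional],
            "hr_rfs": pset.transitions.hr_rfs.to_config(),
            "hr_bcss": pset.transitions.hr_bcss.to_config(),
        },
        "utilities": {
            f.name: getattr(pset.utilities, f.name).to_config()
            for f in dataclasses.fields(pset.utilities)
        },
        "costs": {
            "regimen_6xac": _dump_map(pset.costs.regimen_6xac),
            "regimen_acdc": _dump_map(pset.costs.regimen_acdc),
            "monitoring": _dump_map(pset.costs.monitoring),
            "confirm_incidental": pset.costs.confirm_incidental.to_config(),
            "dfs_annual": _dump_map(pset.costs.dfs_annual),
            "relapse_local": _dump_map(pset.costs.relapse_local),
            "relapse_distant": _dump_map(pset.costs.relapse_distant),
            "bc_death": pset.costs.bc_death.to_config(),
        },
        "screening": {
            **{
                f.name: getattr(pset.contraindications, f.name).to_config()
                for f in dataclasses.fields(pset.contraindications)
                if f.name != "exclusion_components"
            },
            "exclusion_components": list(pset.contraindications.exclusion_components),
        },
        "uptake_current": pset.uptake_current,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def run_log_lines(pset: ParameterSet) -> list[str]:
    """Human-readable account of every parameter after filling/normalisation."""
    lines = [
        "monitoring proportions (normalised): "
        + ", ".join(f"{g}={v:.6f}" for g, v in zip(SUBGROUPS, pset.monitoring.means)),
        f"monitoring dirichlet concentration (moment-matched): {pset.monitoring.concentration:.3f}",
    ]
    for path, p in pset.iter_params():
        extra = ""
        if p.family in ("gamma", "normal", "truncated-normal") and (p.se is None or p.se == 0):
            extra = f" (se filled as 0.25*mean = {p.effective_se:.4g})"
        lines.append(f"{path}: mean={p.mean:.6g} family={p.family}{extra}")
    return lines
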