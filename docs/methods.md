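# Methods

## Model structure

A cohort of women aged 50 with stage II/III ER-positive/HER2-negative
breast cancer enters the model in the disease-free state (DFS) on
completion of neoadjuvant chemotherapy and is followed for 5 one-year
cycles through three health states: DFS, relapse (R; local, regional and
distant pooled) and death (D; breast-cancer and other-cause tracked
separately).  Transitions and accruals happen at cycle end with no
half-cycle correction; per-cycle accruals (life-years, utilities, state
costs) use start-of-cycle occupancy, and one-off transition costs (relapse
episode, breast-cancer death episode) are charged in the cycle of the
transition.  Patients can relapse at most once; R is absorbing until death
("cured" relapses remain in R with the relapse utility and no further
relapse events).  Other-cause mortality applies to every alive state from
an age-indexed life table, ages advancing with model time from 50.

The guided arm is a mixture of four response subgroups fixed at entry —
true favourable (0.525), true unfavourable (0.238), false favourable
(0.168), false unfavourable (0.069) after renormalising the published
proportions (their raw sum is 1.01) — where "true/false" refers to whether
the interim-MRI response call agrees with 5-year relapse-free survival.
Truly classified patients have zero relapse and breast-cancer-death
probability at all times; falsely classified patients follow the observed
yearly relapse probabilities (0.14, 0.29, 0.47, 0.44, 0.40) and, after
relapse, breast-cancer-death probabilities (0, 0.04, 0.12, 0.06, 0.19).
Favourable responders receive 6×AC, unfavourable responders 3×AC+3×DC; the
conventional arm receives 6×AC with its own printed transition
probabilities (relapse 0.03, 0.06, 0.08, 0.05, 0.04; death 0, 0.06, 0.19,
0.09, 0.28).

### Death-probability indexing

The breast-cancer-specific survival curve measures time *from relapse*, so
by default death probabilities after relapse are indexed by years since
relapse, implemented with tunnel sub-states of R (a patient relapsing in
cycle t faces the first-year probability, 0, at the end of cycle t+1).
An alternative model-time indexing — this cycle's probability applies to
every R occupant, the convention a flat spreadsheet Markov model typically
implements — is available via `bc_death_indexing="model-time"`.  The choice
matters: model-time exposes relapsed patients to the later, larger
probabilities sooner and roughly triples the breast-cancer death counts
(e.g. 0.078 vs 0.027 per conventional patient over the horizon).

## Hazard machinery

Per-cycle probabilities derive from cumulative hazards,
`tp(t) = 1 − exp{H(t−u) − H(t)}` with cycle length u = 1 year.  From
individual patient data, `H` is the Nelson–Aalen estimator (increments
d/n at each distinct event time; ties aggregated; an −log Kaplan–Meier
variant is provided for comparison).  A hazard ratio τ of guided vs
conventional treatment produces the counterfactual conventional
probability `1 − exp{(1/τ)·(H(t−u) − H(t))}`.

The base case uses the printed conventional transition probabilities
verbatim.  For sensitivity and probabilistic analyses the guided-side
reference hazard is reconstructed *from those printed values* as
`H_ref = τ_base · H_conv` (τ_base = 0.50 for relapse-free survival, 0.64
for breast-cancer-specific survival), so that a grid or sampled value τ
gives `tp(τ) = 1 − (1 − tp_printed)^(τ_base/τ)`.  This is the only
anchoring under which τ = τ_base reproduces the base case exactly; it is
also numerically consistent with the false-subgroup death probabilities
(e.g. `1 − (1−0.04)^(1/0.64) = 0.062 ≈ 0.06`).  Reconstructing the
conventional relapse curve from the false-subgroup hazards instead is not
possible: those imply a first-year conventional probability of 0.26 at
τ = 0.5, an order of magnitude above the printed 0.03, because the printed
values were estimated from a full trial dataset that is not public.

## Year-1 treatment effects

All patients spend year 1 in DFS under chemotherapy.  Costs: the regimen
total (6×AC €9,279; 3×AC+3×DC €9,975 as the sum of component means — the
printed total is €9,974 due to component rounding), expected
toxicity-treatment costs, and for monitored patients the MRI monitoring
cost (€215) plus the incidental-finding confirmation cost (€149 × 0.176).
Utility: the chemotherapy utility 0.62, substituted for affected fractions
by toxicity utilities and, in monitored patients, by the anxiety utility
0.68 for the incidental-finding fraction.  Toxicities (and the anxiety
episode) occur independently; a patient with several events accrues the
*minimum* of the applicable utilities for the whole cycle.  Substitution —
not decrement subtraction — is used because the published values are
utility levels; substitution also reproduces the published absolute QALY
totals (≈3.5–3.6 discounted), which decrements do not.

Toxicity probabilities are per treatment path: the 6×AC path uses the 3×AC
block probabilities (vomiting 0.05, neutropenia 0.85) with dose-dependent
CHF 0.017 and AML/MDS 0.005; the sequential 3×AC+3×DC path multiplies the
per-block probabilities for vomiting (0.05×0.24) and neutropenia
(0.85×0.72) as independent events, adds hand-foot syndrome (0.22) and
desquamation (0.05), with CHF 0.002 and AML/MDS 0.003.  The CHF
probability under 6×AC uses the 1.7 % figure (not the rounded table value
0.02, and not the count ratio 11/360 ≈ 0.031): only 0.017 reproduces the
published CHF event counts (106 current, 83 full).  Hand-foot syndrome and
desquamation have no curative treatment and carry zero cost.  Interrupted
chemotherapy is assumed not to alter relapse probabilities.  AML/MDS
strikes in model year 5 only: its cost (€112,946) and utility (0.26)
apply to the affected fraction of patients alive in that cycle, with no
induced excess mortality.

Recurring vs one-off costs: DFS follow-up (€2,872/year) accrues in every
DFS cycle; the relapse episode cost (€16,125, the mean of the local and
distant totals) is charged once on entry to R; the breast-cancer death
cost (€8,296) once on that transition.

## Scenarios and incremental outcomes

The target population is 6,306 patients.  MRI contraindications exclude
the sum of the prevalences of impaired renal function (0.0751), ferrous
body parts (0.0582) and claustrophobia (0.0208) — the three
contraindications of the clinical pathway, additive combination, truncated
to whole patients: ⌊6,306 × 0.15412⌋ = 971.  Two notes: the ferrous-parts
prevalence is the event-count mean 0.26/(0.26+4.21) = 0.058 (the printed
"0.58" is inconsistent with the published exclusion totals), and the
gadolinium-related row (0.0003) enters as the per-scan probability of
nephrogenic systemic fibrosis rather than as an a-priori exclusion — this
is the only reading that reproduces both the 971 exclusions and the
published NSF counts (5,335 × 0.0003 ≈ 2).  A complement-product
combination (1 − Π(1 − p)) is available behind a flag; on these inputs it
differs from the additive rule by 0.7 % of the population.

A scenario treats `uptake × (1 − contraindicated fraction)` of the
population with the guided strategy (current: the externally estimated 218
scanned patients; full: 5,335); everyone else, including contraindicated
patients, receives conventional treatment.  Incremental cost and QALYs are
per patient of the scenario cohort versus an all-conventional cohort, so
they scale linearly in the guided fraction.  Decisions use net monetary
benefit at €20,000/QALY (`λ·ΔE − ΔC > 0`; exact ties count as not
cost-effective).

## Parameter uncertainty

Every parameter carries a second-order distribution: beta from event
counts for probabilities and utilities, gamma moment-matched from mean/SE
for costs (shape `(mean/se)²`, scale `se²/mean`), Dirichlet for the four
monitoring proportions (total concentration 154.9, moment-matched on the
first component's SE), truncated normal on (0, ∞) for the RFS hazard
ratio (0.50, SE 0.20) and normal for the BCSS hazard ratio (0.64, SE
0.13; draws clipped positive).  Missing SEs default to 0.25 × mean.
Where a beta needs mean/SE only (CHF utility 0.55, relapse utility 0.73)
it is moment-matched.  The malignant-incidental-finding counts are read as
55 events of 270 findings (beta(55, 215), mean 0.204): the printed mean
0.20 and the downstream malignant counts are consistent only with that
reading.

The PSA draws every parameter jointly once per iteration, shared across
both arms (common random numbers).  The conventional arm's transition
probabilities carry no distribution of their own; by default
(`hr_mode="resample"`) they are re-derived each draw from the sampled
hazard ratios through the rescaling pathway above, propagating the
treatment-effect uncertainty the hazard-ratio distributions encode.
`hr_mode="fixed"` instead holds them at their printed values.  The choice
is recorded in every run manifest.  At 10,000 draws (seed 20160905) the
probability that the guided strategy is cost-effective at €20,000/QALY is
0.87 under `resample` and 0.95 under `fixed` — the difference is almost
entirely draws with τ_RFS ≳ 0.9, where the counterfactual conventional arm
has so few relapses that the guided arm's QALY advantage inverts.

## Synthetic data

Two published inputs are not public and are emulated:

* **Individual patient data** behind the survival curves: event times are
  piecewise exponential with yearly rate `λ_t = −ln(1 − tp_t)` — the
  minimal continuous-time model whose yearly event probabilities equal the
  target transition probabilities — with optional independent yearly
  censoring and censoring at the horizon.  This validates the
  Nelson–Aalen → tp pipeline (round-trip recovery within binomial 95 %
  CIs at n = 2,000) but deliberately contains no covariates, no
  non-proportional hazards and no within-year hazard shape, so passing
  tests say nothing about those features of real trial data.
* **Life table**: `q(age) = 0.0025 × 1.1^(age−50)`, clamped to [0, 1] —
  the order of magnitude of female all-cause mortality at ages 50–55.  It
  is explicitly synthetic; the dominance conclusion is insensitive to the
  base rate anywhere in [0, 0.01] (tested), because other-cause mortality
  strikes both arms nearly symmetrically.

## Numerical choices

* Exclusion counts truncate to whole patients (floor); scan counts are
  candidates minus excluded; unrounded values are always retained in
  machine outputs, and report rounding (counts to integers, fte to 1–3
  significant decimals) is applied only in human-readable views.
* Nelson–Aalen ties aggregate at the shared event time; censored-only
  input yields the zero hazard; the −log KM variant truncates at the last
  event if the survival estimate hits zero.
* A transition probability of 1 in the synthetic generator maps to a
  hazard of −ln(1e−15) (event numerically certain within the year).
* Discounting divides cycle-t amounts by `(1+r)^t` with t starting at 1.
* State occupancies are conserved to 1e−12 over the horizon (tested
  across 1,000 random parameter draws).

## Known limitations

* The incremental QALY gain derivable from the printed inputs is small
  (≈0.006 per patient at full implementation, ≈0.0002 at current):
  the printed conventional relapse probabilities are numerically close to
  the guided arm's overall relapse experience, so most of the guided
  strategy's advantage is on the cost side (fewer relapses and relapse
  episodes, cheaper toxicity profile of the switch regimen), and the
  base case is dominant but not far from the ΔE = 0 axis.  Consequently
  the cost-effectiveness conclusion is sensitive to the RFS hazard ratio:
  grid values τ_RFS ≳ 0.9 flip the decision at €20,000/QALY, and the PSA
  certainty under `hr_mode="resample"` (0.87) sits below the certainty
  under fixed conventional probabilities (0.95).
* Cohort expectations only — no microsimulation, no patient heterogeneity
  beyond the four response subgroups, no adjuvant-therapy modelling, and
  hospital-perspective direct medical costs only (no productivity losses,
  no currency machinery beyond fixed 2013 Euros).
* The resource calculus is static arithmetic (homogeneous of degree 1 in
  the scan count); it does not model queueing or scanner waiting times.
* Whether anxiety and toxicity utilities should stack multiplicatively
  rather than by the minimum rule is undecidable from the sources; the
  minimum rule is a deliberate, documented convention.
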