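# Methods

## Model structure

The package implements a multiple-cohort proportional multistate life
table (PMSLT). A closed population of adults aged 20–100 is divided
into 5-year × sex cohorts (entry ages 20, 25, …, 95; 32 cohorts). Each
cohort is simulated in annual cycles until all members die or reach
age 100; the "lifetime" horizon is therefore 80 calendar years. Two
populations run in parallel — a reference population with current TFA
intake and an intervention population with intake removed (or shifted)
— and every reported outcome is their difference, accumulated by
calendar year since policy start and summed across cohorts.

Rates are held constant over calendar time (the base case assumes
stable intake and epidemiology), there is no migration and no new
entrants at age 20, and the intervention takes full effect from the
first cycle with no phase-in lag.

### Exposure and effect

TFA intake per age–sex stratum is a log-normal distribution
parameterised by moment matching (arithmetic mean and SD), truncated at
m = mean + 10·SD and renormalised; the truncation point is config-
overridable. The upper limit matters in principle because the
log-linear dose–response RR(x) = RR₂^(x/2) grows fast enough that the
untruncated expectation diverges; at ten SDs the truncated mass is
negligible and the expectation is stable. Expected relative risks are
evaluated by adaptive quadrature after substituting the underlying
normal variable (x = e^(μ+σz)), which stays well-conditioned even for
near-degenerate intake distributions where quadrature in x can miss the
density spike entirely; distributions with SD below float resolution of
the mean are treated as point masses and evaluated in closed form.

The primary analysis removes exposure entirely (theoretical minimum
risk exposure level 0 %E), so the PIF reduces to a PAF. A residual
intake of 0.10 ± 0.01 %E — incomplete compliance or ruminant TFA — is a
built-in sensitivity scenario using the general distribution-shift PIF.

### Disease submodel and case fatality

IHD is modelled as a no-remission illness–death process (Well →
Diseased → Dead); remission is fixed at zero, the standard treatment of
IHD as a chronic condition. Case fatality is not published in
burden-of-disease tables and is derived from the stationary identity
f = CSMR / prevalence. An explicit ODE integrator for the
illness–death system (within-year constant rates, exact per-cycle
solution) serves two roles: it is the independent oracle for the
quotient in the test suite, and `consistency_report` uses it to
forward-simulate any input set and measure how far the reproduced
prevalence and CSMR drift from the inputs (strata beyond a configurable
10% relative deviation are flagged). A full iterative fitting of all
four epidemiological parameters simultaneously is deliberately out of
scope; the quotient is the leading-order identity such fits enforce.

### Life-table cycle

Within a cycle at age a the engine: (1) advances reference and
scenario disease occupancies one year in closed form; (2) substitutes
the scenario's IHD mortality proportionally into all-cause mortality,
m′(a) = m(a) − f(a)·p_ref(a) + f(a)·p′(a), clamping at zero with a
logged warning if inputs would drive it negative; (3) accrues
person-years by the trapezoid of start/end survivors (the life-table
L_x convention); (4) computes HALYs as person-years × (1 − morbidity),
where morbidity is the all-cause YLD rate with its IHD share moved in
proportion to modelled prevalence via the disability weight
dw = IHD YLD rate / prevalence (zero where prevalence is zero);
(5) counts incident events as adjusted incidence × susceptible
person-years.

The prevalence entering steps (2)–(5) is the within-cycle average of
the submodel occupancy (trapezoid of start and end of cycle), not the
start-of-cycle value. With start-of-cycle prevalence an annual engine
systematically lags the continuous process by half a cycle and loses
the intervention's entire first-cycle effect; with the mid-cycle
convention the engine agrees with a fine-grained discrete Markov chain
to 0.03% on 10-cycle deaths averted and 0.3% over a lifetime (both
verified in the test suite).

Banded inputs are expanded to single ages piecewise-constantly, counts
split uniformly within bands; this interpolation is a package choice —
how the original banded estimates should be refined to single ages is
genuinely underdetermined. Exposure and relative-risk tables use 15
five-year bands per sex (30 age–sex intake strata); ages 95+ inherit
the terminal band.

### Economics

All costs are in base-year US$ (Ksh rendered at 103 Ksh/US$ in
reports). Components:

* **IHD healthcare**: acute event costs (US$6283 men / US$6083 women
  per event, taken as direct inputs; the pooled MI/angina/cardiac-
  arrest calculation — 0.35/0.55/0.10 for men, 0.20/0.70/0.10 for
  women over US$1996/1237/1026 — is available as an auditable helper,
  since the published totals are not reproducible from the published
  components alone) and prevalent-case care at US$336 per case-year.
* **Other healthcare**: added (or lost) person-years priced at the
  age–sex per-capita expenditure on all non-IHD care. This offset is
  why total healthcare savings are smaller in magnitude than
  IHD-specific savings.
* **Government**: five cost categories over years 1–5; human resources
  and administration (the ongoing monitoring functions) continue at
  their year-5 level thereafter, the others stop.
* **Industry**: a year-1 reformulation lump (£25 000 per product × 99
  products, converted to base-year US$ by a config multiplier) plus an
  annual cost of 1% of the lump.

Discounting multiplies year t by (1+r)^−(t−1) — year 1 is taken as the
present — at 3%/year in the main analysis (0% and 6% as sensitivity
scenarios). HALYs are discounted at the same rate; averted event and
death *counts* are reported undiscounted. The discounting convention
for health outcomes is switchable (`EconSettings.discount_health`).

ICER = net cost / HALYs gained; an implementation-only ICER (excluding
healthcare savings) is also reported. Classification against the WHO
thresholds is half-open (< threshold); negative net cost is cost
saving. ROI = discounted healthcare savings per discounted government
dollar over the matching horizon. Implementation costs are fixed policy
costs, so they do not scale with population size; health outcomes and
healthcare costs scale exactly linearly.

### Probabilistic sensitivity analysis

2000 iterations by default. Per iteration, independently: each
stratum's intake *mean* is replaced by one draw from its log-normal
(the SD is kept fixed; redrawing the full distribution shape is a
config switch), RRs are drawn log-normally around the central value
(clipped below at 1 — a >4σ event at the default log-SD), and each
cost item gets an independent multiplicative normal factor N(1, 0.2)
truncated at zero (truncations are counted and logged). Draws are
reproducible from (seed, iteration) via independent seed sequences.
Point estimates and 95% uncertainty intervals are the 50th and
2.5th/97.5th percentiles by the nearest-rank method on sorted draws
(ties keep the lower index). Failed iterations are recorded and
excluded; more than 1% failures aborts the analysis. No correlation
structure is imposed between parameters.

## Synthetic data

The generator emulates the structure of the study's inputs, not their
values: a young age pyramid (exponentially declining 5-year band
shares, 50/50 sex split, 50 million adults by default), Gompertz
all-cause mortality, IHD incidence rising exponentially with age and a
linearly rising case fatality, with prevalence and CSMR produced by
forward illness–death simulation so the generated epidemiology is
self-consistent by construction (this is what makes the
parameter-recovery tests meaningful rather than circular). Intake
means decline linearly from 0.35 to 0.20 %E across age bands with a
±3% sex contrast and SD = mean/2; the RR is 1.23 per 2 %E at the
youngest band, attenuating linearly to half the excess risk at the
oldest, with log-SD 0.0537 (a 1.11–1.37 95% CI). Cost levels sit at
the published central estimates. The government schedule and the
industry cost multiplier (1.788, combining £→US$ conversion and
inflation to the base year) are back-derived from the published
discounted implementation-cost totals, which the synthetic pipeline
consequently reproduces closely; health outcomes are *not* calibrated
to published results — they are whatever the synthetic epidemiology
implies, and the engine is instead validated by self-consistency (the
5-year incidence reduction must reproduce the PIF-weighted expectation
computed from the bundle's own intake and RR inputs within 0.1
percentage points).

What the generator does not emulate: GBD estimation uncertainty,
correlation between inputs, secular trends, cohort effects, or any
spatial structure. Passing tests therefore demonstrate that the
machinery is correct and internally consistent, not that the synthetic
population reproduces Kenya's actual IHD burden.

## Numerical choices and degenerate inputs

* Annual cycles with within-cycle constant rates solved in closed form;
  the f ≈ i degenerate case of the occupancy transfer term uses its
  analytic limit.
* Zero prevalence with positive CSMR is rejected as inconsistent; 0/0
  yields case fatality 0. Disability weights default to 0 where
  prevalence is 0.
* Negative adjusted mortality (possible only with inconsistent inputs)
  is clamped at 0 and logged.
* PIF quadrature reports its absolute error estimate; RR = 1 and
  degenerate exposures short-circuit to closed forms so null scenarios
  are exact (zero health difference, net cost identically equal to
  implementation cost).
* CSV round trips are bit-exact (`%.17g` on write, round-trip float
  parsing on read).

## Problem sizes

The deterministic pipeline runs 32 cohorts × up to 80 cycles × 2
scenarios in ~15 ms; the full 2000-iteration PSA takes ~30 s on one
CPU. Unit tests run the same population at a 1-million-adult scale
(identical dynamics; outcomes scale linearly), with the full 50-million
default exercised in the acceptance checks.

## Limitations

Closed population and constant rates understate benefits if iTFA
intake or IHD burden would otherwise rise. No indirect or productivity
costs, no budget-impact decomposition by payer, no equity stratification
beyond sex, and no substitution modelling (the RR is a total-effect
estimate against the overall diet; systematic replacement of iTFA by
saturated fat would attenuate the effect). The case-fatality quotient
assumes the illness–death process is near stationarity at each age;
strongly non-stationary inputs will show up in `consistency_report`
rather than being corrected.
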