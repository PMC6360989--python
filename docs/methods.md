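# Methods

`titedose` implements a time-to-event isotonic-regression design for
phase I dose-finding (referred to throughout as TITE-IR), together with
the four rule-based and isotonic comparator designs it is usually
benchmarked against, and a Monte-Carlo harness for operating
characteristics.  This note records the model, the conduct conventions
the package adopts where the design family leaves room for
interpretation, the numerical choices, and what the built-in simulator
does and does not emulate.

## The estimation problem

A phase I trial chooses among dose levels $d_1 < \dots < d_J$ the
maximum tolerated dose (MTD): the dose whose probability of
dose-limiting toxicity (DLT) by a fixed follow-up time $\tau$ is closest
to a target $\pi^*$ without exceeding it.  Toxicity probability is
assumed non-decreasing in dose; no parametric dose-toxicity curve is
assumed.

With $n_j$ patients treated at dose $j$ and $Y_j$ observed toxicities,
the full-information estimate is the isotonic regression of the raw
proportions $Y_j/n_j$.  Waiting $\tau$ months to fully evaluate each
cohort makes such trials slow when $\tau$ is long.  The time-to-event
extension instead uses every patient's partial follow-up at each
decision instant:

$$\hat q_j \;=\; \frac{Y_j + \sum_{i\colon Y_{ij}=0}
\frac{\tau - t_i}{\tau}\,(\pi^* + F^*)}{n_j},$$

where the sum runs over patients at dose $j$ without an observed
toxicity, $t_i \le \tau$ is patient $i$'s elapsed follow-up, and
$F^* \ge 0$ is a conservatism offset.  The term reflects two
assumptions: *a priori* every dose is equally likely to be the MTD
(hence the $\pi^*$-sized prior contribution of an unevaluated patient),
and toxicity onset is uniform on $(0,\tau)$, so surviving $t$ months
event-free removes the fraction $t/\tau$ of the remaining risk.  A
patient with an observed toxicity contributes exactly 1; a patient
fully followed without toxicity contributes 0; with complete follow-up
$\hat q_j = Y_j/n_j$ exactly and $F^*$ drops out.

The $\hat q_j$ over tried doses are smoothed by weighted isotonic
regression (pool-adjacent-violators with weights $n_j$) into a
non-decreasing $\hat p_1 \le \dots \le \hat p_h$, $h$ the highest tried
dose.  The MTD estimate at any analysis is

$$d^{\mathrm{opt}} = \max\,\{d_j : \hat p_j \le \pi^*,\;
|\pi^* - \hat p_j| \text{ minimal}\},$$

ties broken to the highest dose; when no tried dose satisfies
$\hat p_j \le \pi^*$ the lowest dose is reported with a `constrained`
flag.

## Trial conduct conventions

The conduct rules below are the package's resolution of points the
design family's verbal descriptions leave open.  They were fixed by
requiring that the simulated operating characteristics of all five
designs be mutually consistent and reproduce the published benchmark
behaviour of this design family; the empirical consequences of the main
alternatives are noted where instructive.

**TITE-IR (single-patient cohorts, treat on arrival).**  Patient 1 is
treated at $d_1$ at time 0; each later patient is treated at the moment
of arrival, using estimates with follow-ups truncated at that instant.

* *In-trial allocation.*  The next patient receives the tried dose with
  $\hat p_j$ **closest to $\pi^*$ on either side** (ties to the higher
  dose).  Using the one-sided $d^{\mathrm{opt}}$ rule for allocation
  instead makes the design bounce off every freshly escalated dose
  (a single unevaluated patient carries the offset
  $(\pi^*+F^*)(\tau-t)/\tau > \pi^*$ for the first
  $\tau\,F^*/(\pi^*+F^*)$ months), which starves new doses of patients
  and is markedly more conservative than the design is meant to be.
* *Escalation into untried territory.*  Untried doses above $h$ inherit
  $\hat p_h$ (minimal monotone extension), so dose $h+1$ is indicated
  exactly when $\hat p_h \le \pi^*$; escalation additionally requires
  **at least three patients treated at dose $h$**, and never skips a
  level.  A blocked escalation stays at $h$.  Requiring three *fully
  evaluated* patients instead is arithmetically incompatible with
  treating on arrival at realistic accrual (three completed
  evaluations at dose 2 would finish after the last patient has
  already enrolled), freezing every trial at the lowest doses.
* *Toxicity block.*  No escalation above the previous patient's dose
  while that patient has an observed toxicity at the decision instant.
* *Final declaration.*  After $N_{\max}$ patients, all are followed to
  toxicity or $\tau$ and the MTD is $d^{\mathrm{opt}}$ over tried doses
  (one-sided rule, no monotone extension: an untried dose is never
  declared).
* *Duration* is the last arrival time plus $\tau$: in expectation
  $(N_{\max}-1)/\text{rate} + \tau$, about 17.5 months (1.46 yr) at the
  defaults — the design's duration does not depend on the scenario.

**3+3.**  Cohorts of three, fully evaluated: 0/3 toxicities escalates;
more than one declares $d_{j-1}$ (dose 1 at $j=1$); exactly one
triggers an expansion cohort at $d_j$, whose outcome decides between
escalation (0 toxicities) and declaring $d_{j-1}$.  An escalation
indicated at the top dose declares the top dose.  At the sample-size
cap, a clean last cohort declares $d_j$; exactly one toxicity buys a
single terminal expansion cohort ($N_{\max}+3$ patients) and $d_j$ is
declared only if it is toxicity-free.

**Up-and-down design D.**  Cohorts of three, fully evaluated: 0
toxicities escalates (capped at $d_J$), one repeats, more than one
de-escalates (floored at $d_1$), until exactly $N_{\max}$ patients.
The MTD is read off a maximum-likelihood logistic regression of
toxicity on raw dose (highest dose with fitted probability
$\le \pi^*$); when the slope is non-positive or the likelihood is
degenerate (all-same outcomes, separation, non-convergence) the
isotonic fit of the empirical proportions decides instead, with the
usual ties-to-highest rule.

**IR-A / IR-B (isotonic cohort designs).**  Cohorts of three, each
fully evaluated before the next assignment, which uses the same
allocation rule as TITE-IR applied to the isotonic fit of the observed
proportions (closest to target, monotone extension for untried doses,
no skipping), plus the cohort-level toxicity block: no escalation above
the just-evaluated cohort's dose if that cohort had any toxicity.
IR-A stops once the same dose has been given to three consecutive
cohorts and is indicated again, declaring $d^{\mathrm{opt}}$
(one-sided) at that point; IR-B always runs to $N_{\max}$.  An
early-stopped trial ends at the completion of the cohort whose
evaluation triggered the stop.

**Accrual for cohort designs.**  Arrivals queue during follow-up; a
cohort is treated at max(arrival of its third member, previous
cohort's completion) and evaluated for the full window — early
toxicities do not shorten the wait.

## The conservatism offset

$F^*$ trades accuracy for safety: larger values inflate the estimated
toxicity of sparsely observed doses and slow escalation.  The default
0.05 is reproduced by `calibrate_fstar`, which simulates the design
across a grid of offsets under (i) a toxic scenario where only the
lowest dose is acceptable and (ii) a scenario whose MTD is at or near
the top dose, on common replicate streams, together with 3+3 and
up-and-down reference runs.  Candidates whose percentage of patients
treated above the MTD in (i) exceeds the mean reference rate by more
than `over_margin` (default 3 points) are discarded; among the rest,
the smallest offset within `pcd_margin` (default 5 points) of the best
achievable correct-selection probability in (ii) is selected.  The
margin comparison is deliberately made within the safety-feasible set:
the unconstrained offset $F^*=0$ always maximises accuracy, and
measuring the margin against it would veto every safe candidate.

## Simulator

Patient arrivals follow a Poisson process (first arrival at time 0 —
the trial clock starts with patient 1, which is what makes the
expected TITE-IR duration $(N_{\max}-1)/\text{rate}+\tau$).  A patient
treated at a dose with true toxicity-by-$\tau$ probability $p$ is
toxic with probability $p$; onset is uniform on $(0,\tau)$, or drawn
from a user-supplied sampler on $(0,\tau)$ (e.g. a scaled Beta for
early- or late-onset sensitivity analyses).  Ten benchmark scenarios
over six doses (5, 10, 15, 20, 30, 40 mg; $\pi^*=1/3$, $\tau=6$
months, $N_{\max}=24$, 2 arrivals/month) ship with the package.

The simulator does **not** model patient covariates, dropout,
competing risks, inter-patient heterogeneity, delayed toxicity
reporting, or accrual pauses.  Operating characteristics computed here
therefore speak to design behaviour under clean, exchangeable-patient
conditions; none of the passing tests say anything about robustness to
informative dropout or misreported onset times.

## Monte-Carlo harness and problem sizes

`simulate_ocs` aggregates per-design, per-scenario replicates into PCD
(probability of selecting the true MTD), mean toxicities, mean sample
size, mean duration (years), allocation below/at/above the true MTD
(percent of enrolled patients, averaged over replicates), a per-dose
selection profile, and the binomial Monte-Carlo standard error of PCD.
Replicate seeds are spawned from a master seed with NumPy's
`SeedSequence`, so the same (seed, replicate) pair yields the same
stream for every design — designs are compared on common streams.
`flag_against_reference` compares an OC table cell-by-cell against an
external reference with per-column tolerances (defaults: 3 points for
PCD and allocation percentages, 0.4 toxicities, 0.5 patients,
0.15 yr).

The package's own studies use 10,000 replicates per design and
scenario (a full 5-design, 10-scenario study takes about six minutes
on one CPU); property checks in the test suite use 200–2,000
replicates.  The acceptance script (`scripts/acceptance.py`) re-runs
the four contrasted designs at 10,000 replicates and reports the three
aggregate contrasts (PCD advantage over 3+3; duration savings against
IR-A and IR-B).

## Numerical choices

* PAVA is the exact stack algorithm (merge adjacent violating blocks
  into weighted means); ties and pooled blocks share one float, so the
  ties-to-highest selection rule is exact, not tolerance-based.
* The logistic MLE is a Newton-Raphson on aggregated per-dose binomial
  counts (at most $J$ rows), with divergence declared when
  $|b|\,(d_J-d_1) > 200$ or the Hessian is singular — both indicate
  separation, for which the isotonic fallback is the defined
  behaviour.
* Follow-up times are truncated at $\tau$ before estimation; a
  toxicity time equal to an evaluation boundary counts as observed
  (closed interval).
* Degenerate inputs: an empty roster recommends dose 1; a dose with no
  patients carries no estimate and can only be reached through the
  no-skipping escalation rule; configurations with
  $\pi^* + F^* > 1$ are rejected at construction.

## Known limitations

* The conduct conventions above are one consistent resolution of the
  design family's verbal rules; other readings (one-sided in-trial
  allocation, completed-evaluation escalation gates, declaring the
  repeated dose on early stop) are implementable but produce visibly
  different operating characteristics, as noted.
* The up-and-down design's logistic MTD is sensitive to the fallback
  convention in flat dose-toxicity landscapes, where the slope
  estimate's sign is near-random; its PCD in such scenarios should be
  read with that in mind.
* Early-stopped IR-A trials admit more than one defensible duration
  bookkeeping (stop-decision time vs last-enrollment time); we use the
  stop-decision time, the earliest instant the stopping condition is
  decidable.
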