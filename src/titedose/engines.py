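"""Event-driven conduct of a single dose-finding trial per design.

Five designs are implemented:

``TITE-IR``
    The time-to-event isotonic design.  Patients are treated immediately
    on arrival at the dose indicated by the partial-follow-up estimator,
    subject to safety rules: the trial starts at the lowest dose, untried
    doses are never skipped, escalation into untried territory requires
    three patients at the highest tried dose with its estimate at or
    below the target, and no escalation is allowed while the most
    recently treated patient has an observed toxicity.
``3+3``
    The classical rule-based design (escalate on 0/3, expand on 1/3,
    stop on >1/3), with a terminal expansion cohort allowed past the
    sample-size cap.
``UD``
    Up-and-down design D: cohorts of three with escalate / repeat /
    de-escalate rules and a terminal logistic-regression fit to choose
    the maximum tolerated dose.
``IR-A`` / ``IR-B``
    Isotonic-regression designs on fully followed cohorts of three,
    with (A) and without (B) early stopping once the same dose has been
    given to three consecutive cohorts and is indicated again.

Cohort-based designs queue arrivals during follow-up: a cohort starts
when three patients are available and the previous cohort's evaluation
window has elapsed; the whole window ``tau`` is always waited out.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np

from .estimation import (
    DoseDecision,
    PatientRecord,
    TrialConfig,
    estimate_all,
    pava,
    select_dose,
)
from .patients import OutcomeDraw, Scenario, TimeSampler, draw_outcome, generate_arrivals

__all__ = [
    "TrialResult",
    "DESIGNS",
    "run_trial",
    "run_tite_ir",
    "run_three_plus_three",
    "run_up_down_d",
    "run_ir",
    "fit_logistic_mtd",
]

#: optional hook replacing the Bernoulli/uniform outcome draw, for
#: scripted conduct tests: (dose_index, rng) -> OutcomeDraw
OutcomeHook = Callable[[int, np.random.Generator], OutcomeDraw]

DESIGNS = ("TITE-IR", "3+3", "UD", "IR-A", "IR-B")


@dataclass
class _Latent:
    """Full simulated truth for one patient (not all observed at once)."""

    index: int
    arrival_time: float
    treatment_time: float
    dose_index: int
    toxicity: int
    toxicity_time: float | None

    def observe(self, at_time: float, tau: float) -> PatientRecord:
        elapsed = max(0.0, at_time - self.treatment_time)
        followup = min(elapsed, tau)
        if self.toxicity and self.toxicity_time is not None and self.toxicity_time <= followup:
            return PatientRecord(
                index=self.index,
                arrival_time=self.arrival_time,
                dose_index=self.dose_index,
                toxicity=1,
                toxicity_time=self.toxicity_time,
                followup=followup,
                treatment_time=self.treatment_time,
            )
        return PatientRecord(
            index=self.index,
            arrival_time=self.arrival_time,
            dose_index=self.dose_index,
            toxicity=0,
            toxicity_time=None,
            followup=followup,
            treatment_time=self.treatment_time,
        )


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated (or conducted) trial."""

    design: str
    mtd_index: int
    roster: tuple[PatientRecord, ...]
    n_enrolled: int
    n_toxicities: int
    duration: float  # months, first enrollment to last evaluation completion
    allocation: tuple[int, int, int]  # patients below / at / above the true MTD
    constrained: bool = False  # final recommendation fell back to dose 1

    @property
    def duration_years(self) -> float:
        return self.duration / 12.0

    def to_json(self) -> str:
        payload = asdict(self)
        payload["roster"] = [asdict(p) for p in self.roster]
        return json.dumps(payload)


def _allocation(rosters: Sequence[PatientRecord], true_mtd: int) -> tuple[int, int, int]:
    below = sum(1 for p in rosters if p.dose_index < true_mtd)
    at = sum(1 for p in rosters if p.dose_index == true_mtd)
    above = sum(1 for p in rosters if p.dose_index > true_mtd)
    return below, at, above


def _draw(
    scenario: Scenario,
    dose_index: int,
    tau: float,
    rng: np.random.Generator,
    outcome_hook: OutcomeHook | None,
    time_sampler: TimeSampler | None,
) -> OutcomeDraw:
    if outcome_hook is not None:
        return outcome_hook(dose_index, rng)
    return draw_outcome(scenario.true_probs[dose_index - 1], tau, rng, time_sampler)


def _finalize(
    design: str,
    scenario: Scenario,
    config: TrialConfig,
    latents: list[_Latent],
    mtd: int,
    duration: float,
    constrained: bool,
) -> TrialResult:
    end = max(l.treatment_time for l in latents) + config.tau
    roster = tuple(l.observe(end, config.tau) for l in latents)
    return TrialResult(
        design=design,
        mtd_index=mtd,
        roster=roster,
        n_enrolled=len(latents),
        n_toxicities=sum(p.toxicity for p in roster),
        duration=duration,
        allocation=_allocation(roster, scenario.true_mtd(config.target)),
        constrained=constrained,
    )


# ---------------------------------------------------------------------------
# TITE-IR


def _closest_to_target(phat: Sequence[float], target: float, dose_indices: Sequence[int]) -> int:
    """Dose with estimate closest to the target on either side, ties to
    the higher dose (the in-trial allocation rule)."""
    best, best_gap = 0, np.inf
    for k, p in enumerate(phat):
        gap = abs(target - p)
        if gap <= best_gap:
            best, best_gap = k, gap
    return dose_indices[best]


def tite_next_dose(
    roster: Sequence[PatientRecord],
    config: TrialConfig,
) -> tuple[DoseDecision, list]:
    """Dose recommendation for the next patient given the observed roster.

    The roster holds the observed state (toxicity status and truncated
    follow-up) of every treated patient at the decision instant, most
    recently treated last.  An empty roster recommends the lowest dose.

    In-trial allocation treats at the tried dose whose smoothed estimate
    is closest to the target (ties to the higher dose).  Escalation into
    untried territory — one level above the highest tried dose h, never
    skipping — happens only when the indicated dose is h itself, its
    estimate does not exceed the target, and at least three patients
    have been treated at h; a blocked escalation stays at h.  No
    escalation above the previous patient's dose is allowed while that
    patient has an observed toxicity.  Returns the decision together
    with the per-dose summaries it was based on; the ``constrained``
    flag marks decisions where a safety rule overrode the indicated
    escalation.
    """
    if len(roster) == 0:
        return DoseDecision(dose_index=1, constrained=False), []
    summaries = estimate_all(roster, config)
    tried = [s.dose_index for s in summaries]
    phat = [s.phat for s in summaries]
    h = tried[-1]
    cand = _closest_to_target(phat, config.target, tried)
    # no estimated dose meets the target: the trial is pinned low
    constrained = all(p > config.target for p in phat)
    if cand == h and h < config.n_doses:
        # untried doses inherit phat_h under the minimal monotone
        # extension, so h+1 is indicated exactly when phat_h <= target;
        # entering untried territory needs three patients at h first
        if phat[-1] <= config.target:
            if summaries[-1].n >= 3:
                cand = h + 1
            else:
                constrained = True
    current = roster[-1].dose_index
    if cand > current and roster[-1].toxicity:
        cand = current  # no escalation past a just-observed toxicity
        constrained = True
    return DoseDecision(dose_index=cand, constrained=constrained), summaries


def run_tite_ir(
    scenario: Scenario,
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    outcome_hook: OutcomeHook | None = None,
    time_sampler: TimeSampler | None = None,
    audit: list | None = None,
) -> TrialResult:
    """Simulate one trial under the time-to-event isotonic design.

    Patients are treated immediately on arrival; dose decisions use the
    partial-follow-up estimator with follow-ups truncated at the arrival
    instant (see :func:`tite_next_dose`).  After ``n_max`` patients all
    are followed to ``tau`` and the declared MTD is the tried dose with
    estimate closest to the target without exceeding it.
    """
    if config.cohort_size != 1:
        raise ValueError("the time-to-event design treats single-patient cohorts")
    rng = np.random.default_rng(rng)
    arrivals = generate_arrivals(config.n_max, config.accrual_rate, rng)
    latents: list[_Latent] = []
    for i, t in enumerate(arrivals):
        if i == 0:
            decision = DoseDecision(dose_index=1)
            summaries = []
        else:
            snap = [l.observe(t, config.tau) for l in latents]
            decision, summaries = tite_next_dose(snap, config)
        dose = decision.dose_index
        out = _draw(scenario, dose, config.tau, rng, outcome_hook, time_sampler)
        latents.append(
            _Latent(
                index=i + 1,
                arrival_time=float(t),
                treatment_time=float(t),
                dose_index=dose,
                toxicity=out.toxicity,
                toxicity_time=out.toxicity_time,
            )
        )
        if audit is not None:
            audit.append(
                {
                    "time": float(t),
                    "patient": i + 1,
                    "dose": dose,
                    "constrained": decision.constrained,
                    "estimates": [
                        {"dose": s.dose_index, "n": s.n, "y": s.y,
                         "qhat": s.qhat, "phat": s.phat}
                        for s in summaries
                    ],
                }
            )
    end = arrivals[-1] + config.tau
    final = [l.observe(end, config.tau) for l in latents]
    summaries = estimate_all(final, config)
    decision = select_dose([s.phat for s in summaries], config, [s.dose_index for s in summaries])
    return _finalize(
        "TITE-IR", scenario, config, latents, decision.dose_index, end, decision.constrained
    )


# ---------------------------------------------------------------------------
# cohort plumbing


class _CohortAccrual:
    """Queued Poisson accrual for cohort designs: a cohort of three is
    treated at max(arrival of its third member, previous completion),
    and is evaluated for the full window before the next decision."""

    def __init__(self, config: TrialConfig, rng: np.random.Generator, max_patients: int):
        self.arrivals = generate_arrivals(max_patients, config.accrual_rate, rng)
        self.tau = config.tau
        self.used = 0
        self.completion = 0.0

    def next_cohort_start(self) -> float:
        third = self.arrivals[self.used + 2]
        start = max(float(third), self.completion)
        self.completion = start + self.tau
        return start


def _enroll_cohort(
    accrual: _CohortAccrual,
    dose: int,
    scenario: Scenario,
    config: TrialConfig,
    rng: np.random.Generator,
    latents: list[_Latent],
    outcome_hook: OutcomeHook | None,
    time_sampler: TimeSampler | None,
) -> int:
    """Treat one fully evaluated cohort of three; returns its toxicity count."""
    start = accrual.next_cohort_start()
    ntox = 0
    for _ in range(3):
        arr = float(accrual.arrivals[accrual.used])
        out = _draw(scenario, dose, config.tau, rng, outcome_hook, time_sampler)
        latents.append(
            _Latent(
                index=accrual.used + 1,
                arrival_time=arr,
                treatment_time=start,
                dose_index=dose,
                toxicity=out.toxicity,
                toxicity_time=out.toxicity_time,
            )
        )
        ntox += out.toxicity
        accrual.used += 1
    return ntox


# ---------------------------------------------------------------------------
# 3 + 3


def run_three_plus_three(
    scenario: Scenario,
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    outcome_hook: OutcomeHook | None = None,
    time_sampler: TimeSampler | None = None,
) -> TrialResult:
    """Simulate one classical 3+3 trial.

    Per cohort of three at dose j: 0 toxicities escalates, more than one
    declares dose j-1 (dose 1 when j = 1), exactly one triggers an
    expansion cohort at dose j whose outcome decides between escalation
    (0 toxicities) and declaring dose j-1.  An escalation indicated at
    the top dose declares the top dose.  Once the sample-size cap is
    reached: 0 toxicities in the last cohort declares dose j; exactly
    one buys a single extra expansion cohort (sample size cap + 3) and
    dose j is declared only if it is toxicity-free.
    """
    if config.cohort_size != 3:
        raise ValueError("the 3+3 design treats cohorts of three")
    rng = np.random.default_rng(rng)
    accrual = _CohortAccrual(config, rng, config.n_max + 3)
    latents: list[_Latent] = []
    j = 1
    J = config.n_doses
    mtd: int | None = None
    expansion = False  # next cohort is the expansion for a 1/3 at dose j
    while mtd is None:
        ntox = _enroll_cohort(
            accrual, j, scenario, config, rng, latents, outcome_hook, time_sampler
        )
        n_enrolled = len(latents)
        if expansion:
            expansion = False
            if ntox == 0:
                # escalation indicated: blocked by the cap or the top dose,
                # in which case dose j is declared
                if n_enrolled >= config.n_max or j == J:
                    mtd = j
                else:
                    j += 1
            else:
                mtd = max(j - 1, 1)
        else:
            if ntox == 0:
                if n_enrolled >= config.n_max or j == J:
                    mtd = j
                else:
                    j += 1
            elif ntox == 1:
                # expansion at dose j; past the cap this is the single
                # terminal expansion (sample size n_max + 3)
                expansion = True
            else:
                mtd = max(j - 1, 1)
    return _finalize("3+3", scenario, config, latents, mtd, accrual.completion, False)


# ---------------------------------------------------------------------------
# up-and-down design D


def _logistic_mle(dose_levels: np.ndarray, n: np.ndarray, y: np.ndarray,
                  max_iter: int = 50, tol: float = 1e-10) -> tuple[float, float, bool]:
    """Newton-Raphson ML fit of a two-parameter logistic dose-toxicity
    model on aggregated per-dose binomial counts.  Returns (intercept,
    slope, converged); non-convergence covers separation and diverging
    estimates."""
    x = np.asarray(dose_levels, dtype=float)
    beta = np.zeros(2)
    ybar = y.sum() / n.sum()
    if 0.0 < ybar < 1.0:
        beta[0] = math.log(ybar / (1.0 - ybar))
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - n * mu)
        w = n * mu * (1.0 - mu)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta[0], beta[1], False
        beta = beta + step
        if not np.all(np.isfinite(beta)) or abs(beta[1]) * (x.max() - x.min()) > 200:
            return beta[0], beta[1], False  # separation / divergence
        if np.max(np.abs(step)) < tol:
            return float(beta[0]), float(beta[1]), True
    return float(beta[0]), float(beta[1]), False


def fit_logistic_mtd(roster: Sequence[PatientRecord], config: TrialConfig) -> DoseDecision:
    """MTD from a terminal logistic regression of toxicity on raw dose.

    Fits ``logit P(tox) = a + b * dose`` by maximum likelihood and
    returns the highest dose whose fitted probability is closest to the
    target without exceeding it.  When the slope is non-positive or the
    fit fails (separation, degenerate all-same outcomes) it falls back
    to the isotonic fit of the empirical per-dose proportions.
    """
    if len(roster) == 0:
        raise ValueError("roster is empty")
    by_dose: dict[int, list[PatientRecord]] = {}
    for p in roster:
        by_dose.setdefault(p.dose_index, []).append(p)
    tried = sorted(by_dose)
    n = np.array([len(by_dose[j]) for j in tried], dtype=float)
    y = np.array([sum(p.toxicity for p in by_dose[j]) for j in tried], dtype=float)
    levels = np.array([config.dose_levels[j - 1] for j in tried])
    degenerate = y.sum() == 0 or y.sum() == n.sum() or len(tried) < 2
    if not degenerate:
        a, b, converged = _logistic_mle(levels, n, y)
        if converged and b > 0:
            all_levels = np.asarray(config.dose_levels)
            fitted = 1.0 / (1.0 + np.exp(-(a + b * all_levels)))
            return select_dose(fitted, config, list(range(1, config.n_doses + 1)))
    # fallback: isotonic fit of the observed proportions at tried doses
    phat = pava(y / n, n)
    return select_dose(phat, config, tried)


def run_up_down_d(
    scenario: Scenario,
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    outcome_hook: OutcomeHook | None = None,
    time_sampler: TimeSampler | None = None,
) -> TrialResult:
    """Simulate one up-and-down design D trial: cohorts of three with
    escalate (0 toxicities) / repeat (1) / de-escalate (>1) moves until
    the sample-size cap, then a logistic-regression MTD."""
    if config.cohort_size != 3:
        raise ValueError("the up-and-down design treats cohorts of three")
    if config.n_max % 3 != 0:
        raise ValueError("n_max must be a multiple of the cohort size")
    rng = np.random.default_rng(rng)
    accrual = _CohortAccrual(config, rng, config.n_max)
    latents: list[_Latent] = []
    j = 1
    for _ in range(config.n_max // 3):
        ntox = _enroll_cohort(
            accrual, j, scenario, config, rng, latents, outcome_hook, time_sampler
        )
        if ntox == 0:
            j = min(j + 1, config.n_doses)
        elif ntox >= 2:
            j = max(j - 1, 1)
    end = accrual.completion
    roster = [l.observe(end, config.tau) for l in latents]
    decision = fit_logistic_mtd(roster, config)
    return _finalize(
        "UD", scenario, config, latents, decision.dose_index, end, decision.constrained
    )


# ---------------------------------------------------------------------------
# isotonic-regression designs on fully followed cohorts


def run_ir(
    scenario: Scenario,
    config: TrialConfig,
    early_stop: bool,
    rng: np.random.Generator | int | None = None,
    outcome_hook: OutcomeHook | None = None,
    time_sampler: TimeSampler | None = None,
) -> TrialResult:
    """Simulate one isotonic-regression trial on fully followed cohorts.

    Each cohort of three is followed for the full window before the next
    assignment, which is the isotonic recommendation on the observed
    proportions (no skipping; escalation only from the highest tried
    dose when its estimate is at or below the target, and never past a
    cohort with an observed toxicity).  With ``early_stop`` the trial
    stops once the same dose has been given to three consecutive
    cohorts and is indicated for the next.
    """
    if config.cohort_size != 3:
        raise ValueError("the isotonic cohort designs treat cohorts of three")
    if config.n_max % 3 != 0:
        raise ValueError("n_max must be a multiple of the cohort size")
    rng = np.random.default_rng(rng)
    accrual = _CohortAccrual(config, rng, config.n_max)
    latents: list[_Latent] = []
    j = 1
    history: list[int] = []
    mtd: int | None = None
    constrained = False
    for _ in range(config.n_max // 3):
        ntox = _enroll_cohort(
            accrual, j, scenario, config, rng, latents, outcome_hook, time_sampler
        )
        history.append(j)
        # full evaluation: observe everyone at this cohort's completion
        snap = [l.observe(accrual.completion, config.tau) for l in latents]
        summaries = estimate_all(snap, config)
        tried = [s.dose_index for s in summaries]
        phat = [s.phat for s in summaries]
        h = tried[-1]
        nxt = _closest_to_target(phat, config.target, tried)
        if nxt == h and h < config.n_doses and phat[-1] <= config.target:
            nxt = h + 1
        if nxt > j and ntox > 0:
            nxt = j  # no escalation past a cohort with an observed toxicity
        if (
            early_stop
            and len(history) >= 3
            and history[-1] == history[-2] == history[-3] == nxt
        ):
            # stable allocation: stop and declare by the closest-below rule
            decision = select_dose(phat, config, tried)
            mtd, constrained = decision.dose_index, decision.constrained
            break
        j = nxt
    if mtd is None:
        snap = [l.observe(accrual.completion, config.tau) for l in latents]
        summaries = estimate_all(snap, config)
        decision = select_dose(
            [s.phat for s in summaries], config, [s.dose_index for s in summaries]
        )
        mtd, constrained = decision.dose_index, decision.constrained
    return _finalize(
        "IR-A" if early_stop else "IR-B",
        scenario,
        config,
        latents,
        mtd,
        accrual.completion,
        constrained,
    )


# ---------------------------------------------------------------------------


def run_trial(
    design: str,
    scenario: Scenario,
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> TrialResult:
    """Run one trial of the named design, adjusting the cohort size to
    the design's convention (1 for TITE-IR, 3 otherwise)."""
    import dataclasses

    if design == "TITE-IR":
        cfg = dataclasses.replace(config, cohort_size=1)
        return run_tite_ir(scenario, cfg, rng, **kwargs)
    cfg = dataclasses.replace(config, cohort_size=3)
    if design == "3+3":
        return run_three_plus_three(scenario, cfg, rng, **kwargs)
    if design == "UD":
        return run_up_down_d(scenario, cfg, rng, **kwargs)
    if design == "IR-A":
        return run_ir(scenario, cfg, True, rng, **kwargs)
    if design == "IR-B":
        return run_ir(scenario, cfg, False, rng, **kwargs)
    raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
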