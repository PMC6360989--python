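"""Core estimation for time-to-event isotonic dose finding.

The estimator treats a patient still under follow-up as a partial
observation: a patient with no toxicity after ``t`` of ``tau`` months
contributes ``((tau - t)/tau) * (target + f_star)`` to the toxicity count
at their dose, reflecting a uniform time-to-toxicity assumption over
``(0, tau)`` and a flat prior belief that every dose is equally likely to
be the maximum tolerated dose.  A patient with an observed toxicity
contributes exactly 1; a patient fully followed without toxicity
contributes 0, so with complete follow-up the estimator reduces to the
raw proportion ``y_j / n_j``.

Raw per-dose estimates are smoothed into a non-decreasing dose-toxicity
curve by weighted isotonic regression (pool-adjacent-violators, weights
``n_j``), and the recommended dose is the one with smoothed probability
closest to the target without exceeding it, ties broken upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TrialConfig",
    "PatientRecord",
    "DoseSummary",
    "DoseDecision",
    "compute_qhat",
    "pava",
    "select_dose",
    "estimate_all",
]

DEFAULT_DOSE_LEVELS = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class TrialConfig:
    """All design parameters of a dose-finding trial.

    Parameters
    ----------
    dose_levels
        Raw dose values (e.g. mg), strictly increasing.  Length defines
        the number of dose levels ``J``.
    target
        Target toxicity probability (``pi*``), in (0, 1).
    tau
        Follow-up window for toxicity, in months.
    f_star
        Non-negative conservatism offset added to ``target`` in the
        partial-follow-up contribution; larger values make escalation
        harder.  ``target + f_star`` must not exceed 1.
    n_max
        Maximum number of patients enrolled.
    accrual_rate
        Expected patient arrivals per month (Poisson process).
    cohort_size
        1 for the time-to-event design, 3 for the cohort-based
        comparators.
    """

    dose_levels: tuple[float, ...] = DEFAULT_DOSE_LEVELS
    target: float = 1.0 / 3.0
    tau: float = 6.0
    f_star: float = 0.05
    n_max: int = 24
    accrual_rate: float = 2.0
    cohort_size: int = 1

    def __post_init__(self) -> None:
        levels = tuple(float(d) for d in self.dose_levels)
        object.__setattr__(self, "dose_levels", levels)
        if len(levels) < 1:
            raise ValueError("at least one dose level is required")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("dose_levels must be strictly increasing")
        if not 0.0 < self.target < 1.0:
            raise ValueError("target must lie strictly between 0 and 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.f_star < 0:
            raise ValueError("f_star must be non-negative")
        if self.target + self.f_star > 1.0:
            raise ValueError("target + f_star exceeds 1; the partial-follow-up "
                             "contribution would not be a probability")
        if self.n_max < 1:
            raise ValueError("n_max must be a positive integer")
        if self.accrual_rate <= 0:
            raise ValueError("accrual_rate must be positive")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be a positive integer")

    @property
    def n_doses(self) -> int:
        return len(self.dose_levels)


@dataclass(frozen=True)
class PatientRecord:
    """One subject's state as observed at a decision time.

    ``toxicity`` is the *observed* binary toxicity indicator at the
    decision time; ``followup`` is the elapsed on-study evaluation time,
    truncated at ``tau``.  ``toxicity_time`` (months after treatment
    start) is defined only when ``toxicity == 1``.
    """

    index: int
    arrival_time: float
    dose_index: int  # 1-based
    toxicity: int
    toxicity_time: float | None = None
    followup: float = 0.0
    treatment_time: float | None = None


@dataclass(frozen=True)
class DoseSummary:
    """Per-dose counts and estimates at a decision time."""

    dose_index: int
    n: int
    y: int
    qhat: float
    phat: float


@dataclass(frozen=True)
class DoseDecision:
    """A dose recommendation; ``constrained`` is set when safety rules
    overrode the unconstrained closest-to-target choice (every estimated
    dose exceeded the target)."""

    dose_index: int
    constrained: bool = False


def compute_qhat(patients_at_dose: Sequence[PatientRecord], config: TrialConfig) -> float:
    """Raw toxicity-probability estimate for one dose from partial follow-up.

    ``qhat = (Y + sum_{i: Y_i = 0} ((tau - t_i)/tau) * (target + f_star)) / n``

    where the sum runs over patients without an observed toxicity and
    ``t_i`` is each such patient's follow-up time (truncated at ``tau``).
    """
    if len(patients_at_dose) == 0:
        raise ValueError("qhat is undefined for a dose with no treated patients")
    doses = {p.dose_index for p in patients_at_dose}
    if len(doses) != 1:
        raise ValueError(f"patients span multiple doses: {sorted(doses)}")
    tau = config.tau
    offset = config.target + config.f_star
    numerator = 0.0
    for p in patients_at_dose:
        if p.toxicity:
            if p.toxicity_time is not None and p.toxicity_time > tau:
                raise ValueError("observed toxicity_time exceeds the follow-up window")
            numerator += 1.0
        else:
            if not 0.0 <= p.followup <= tau:
                raise ValueError(f"follow-up {p.followup} outside [0, tau]")
            numerator += (tau - p.followup) / tau * offset
    return numerator / len(patients_at_dose)


def pava(values: Sequence[float], weights: Sequence[float]) -> np.ndarray:
    """Weighted least-squares isotonic (non-decreasing) fit.

    Pool-adjacent-violators: whenever adjacent values violate
    monotonicity they are merged into a block valued at the
    weight-weighted mean, until the sequence is non-decreasing.  Output
    has the input length and is constant on pooled blocks.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.ndim != 1 or w.ndim != 1 or v.shape != w.shape:
        raise ValueError("values and weights must be 1-d and of equal length")
    if v.size == 0:
        raise ValueError("pava requires at least one value")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    # blocks as (mean, weight, count) on a stack
    means: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for x, wx in zip(v, w):
        means.append(float(x))
        wts.append(float(wx))
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), counts.pop()
            wtot = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wtot)
            wts.append(wtot)
            counts.append(c1 + c2)
    return np.repeat(means, counts)


def select_dose(
    phat: Sequence[float],
    config: TrialConfig,
    dose_indices: Sequence[int] | None = None,
) -> DoseDecision:
    """Pick the dose whose smoothed toxicity probability is closest to the
    target without exceeding it; ties go to the highest dose.

    ``phat`` covers the admissible (estimated) doses in increasing dose
    order; ``dose_indices`` maps positions to 1-based dose indices
    (defaults to ``1..len(phat)``).  When every dose exceeds the target
    the lowest dose is returned with the ``constrained`` flag set.
    """
    p = np.asarray(phat, dtype=float)
    if p.size == 0:
        raise ValueError("admissible dose set is empty")
    if dose_indices is None:
        idx = list(range(1, p.size + 1))
    else:
        idx = [int(i) for i in dose_indices]
        if len(idx) != p.size:
            raise ValueError("dose_indices length does not match phat")
    target = config.target
    best: int | None = None
    best_gap = np.inf
    for k in range(p.size):
        if p[k] <= target:
            gap = target - p[k]
            # <= keeps the highest dose on exact ties (pooled blocks share a float)
            if gap <= best_gap:
                best, best_gap = k, gap
    if best is None:
        return DoseDecision(dose_index=idx[0], constrained=True)
    return DoseDecision(dose_index=idx[best], constrained=False)


def estimate_all(
    roster: Sequence[PatientRecord], config: TrialConfig
) -> list[DoseSummary]:
    """Per-dose summaries at a decision time: raw estimates per tried
    dose, then the isotonic fit with weights ``n_j`` across tried doses
    in increasing dose order.  Untried doses carry no estimate."""
    if len(roster) == 0:
        raise ValueError("roster is empty")
    by_dose: dict[int, list[PatientRecord]] = {}
    for p in roster:
        by_dose.setdefault(p.dose_index, []).append(p)
    tried = sorted(by_dose)
    qhats = [compute_qhat(by_dose[j], config) for j in tried]
    ns = [len(by_dose[j]) for j in tried]
    phats = pava(qhats, ns)
    return [
        DoseSummary(
            dose_index=j,
            n=ns[k],
            y=sum(p.toxicity for p in by_dose[j]),
            qhat=qhats[k],
            phat=float(phats[k]),
        )
        for k, j in enumerate(tried)
    ]
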