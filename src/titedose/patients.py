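"""Patient-level simulation: accrual, toxicity outcomes, and scenarios.

Arrivals follow a Poisson process (the first patient arrives at trial
start, time 0).  A patient treated at a dose with true toxicity-by-tau
probability ``p`` experiences a toxicity with probability ``p``; when a
toxicity occurs its onset time is uniform on ``(0, tau)`` unless a
custom time-to-toxicity sampler is supplied.

The ten benchmark dose-toxicity scenarios used throughout the package
are shipped as :func:`scenario_table`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Scenario",
    "OutcomeDraw",
    "TimeSampler",
    "generate_arrivals",
    "draw_outcome",
    "scenario_table",
    "scenarios_to_csv",
    "scenarios_from_csv",
    "scenarios_to_yaml",
    "scenarios_from_yaml",
]

#: signature of a pluggable time-to-toxicity sampler: (tau, rng) -> time in (0, tau)
TimeSampler = Callable[[float, np.random.Generator], float]


@dataclass(frozen=True)
class Scenario:
    """A named vector of true toxicity-by-tau probabilities per dose."""

    name: str
    true_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.true_probs)
        object.__setattr__(self, "true_probs", probs)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("toxicity probabilities must lie in [0, 1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("toxicity probabilities must be non-decreasing")

    @property
    def n_doses(self) -> int:
        return len(self.true_probs)

    def true_mtd(self, target: float = 1.0 / 3.0) -> int:
        """1-based index of the dose with probability closest to the
        target without exceeding it, ties to the highest dose; dose 1
        when even the lowest dose is above the target."""
        best, best_gap = None, np.inf
        for k, p in enumerate(self.true_probs):
            if p <= target and (target - p) <= best_gap:
                best, best_gap = k, target - p
        return 1 if best is None else best + 1


@dataclass(frozen=True)
class OutcomeDraw:
    """One patient's simulated outcome: toxicity indicator and, when
    toxic, the onset time in months after treatment start."""

    toxicity: int
    toxicity_time: float | None = None


def generate_arrivals(n: int, rate: float, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Arrival times (months) of ``n`` patients under Poisson accrual.

    The first patient arrives at time 0; subsequent inter-arrival gaps
    are independent exponentials with mean ``1/rate``.
    """
    if n < 1:
        raise ValueError("need at least one arrival")
    if rate <= 0:
        raise ValueError("accrual rate must be positive")
    rng = np.random.default_rng(rng)
    gaps = rng.exponential(scale=1.0 / rate, size=n - 1)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def draw_outcome(
    p: float,
    tau: float,
    rng: np.random.Generator | int | None = None,
    time_sampler: TimeSampler | None = None,
) -> OutcomeDraw:
    """Draw one patient's toxicity outcome at a dose with true
    toxicity-by-``tau`` probability ``p``.

    Toxicity is Bernoulli(``p``); a toxic patient's onset time is
    uniform on ``(0, tau)``, or drawn from ``time_sampler(tau, rng)``
    when one is supplied (any density on ``(0, tau)``).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("toxicity probability outside [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(rng)
    if rng.random() < p:
        t = time_sampler(tau, rng) if time_sampler is not None else rng.uniform(0.0, tau)
        if not 0.0 < t < tau:
            raise ValueError("time-to-toxicity sampler returned a time outside (0, tau)")
        return OutcomeDraw(toxicity=1, toxicity_time=float(t))
    return OutcomeDraw(toxicity=0)


_SCENARIO_PROBS: tuple[tuple[float, ...], ...] = (
    (0.05, 0.10, 0.20, 0.30, 0.50, 0.70),
    (0.09, 0.16, 0.27, 0.38, 0.57, 0.75),
    (0.30, 0.40, 0.52, 0.61, 0.76, 0.87),
    (0.00, 0.00, 0.04, 0.09, 0.25, 0.49),
    (0.20, 0.90, 0.90, 0.90, 0.90, 0.90),
    (0.10, 0.20, 0.90, 0.90, 0.90, 0.90),
    (0.30, 0.30, 0.50, 0.50, 0.50, 0.50),
    (0.00, 0.00, 0.03, 0.05, 0.11, 0.33),
    (0.12, 0.18, 0.22, 0.25, 0.33, 0.50),
    (0.10, 0.10, 0.20, 0.20, 0.40, 0.40),
)


def scenario_table() -> list[Scenario]:
    """The ten benchmark scenarios (true toxicity probabilities by tau
    for six dose levels) used in the operating-characteristics study."""
    return [Scenario(name=str(k + 1), true_probs=probs) for k, probs in enumerate(_SCENARIO_PROBS)]


def scenarios_to_csv(scenarios: Sequence[Scenario]) -> str:
    """Serialize scenarios to CSV text (columns: scenario, p1..pJ)."""
    buf = io.StringIO()
    j = scenarios[0].n_doses
    writer = csv.writer(buf)
    writer.writerow(["scenario"] + [f"p{k + 1}" for k in range(j)])
    for s in scenarios:
        writer.writerow([s.name] + [repr(p) for p in s.true_probs])
    return buf.getvalue()


def scenarios_from_csv(text: str) -> list[Scenario]:
    reader = csv.DictReader(io.StringIO(text))
    out = []
    for row in reader:
        probs = tuple(float(v) for k, v in row.items() if k != "scenario")
        out.append(Scenario(name=row["scenario"], true_probs=probs))
    return out


def scenarios_to_yaml(scenarios: Sequence[Scenario]) -> str:
    import yaml

    payload = {s.name: list(s.true_probs) for s in scenarios}
    return yaml.safe_dump(payload, sort_keys=False)


def scenarios_from_yaml(text: str) -> list[Scenario]:
    import yaml

    payload = yaml.safe_load(text)
    return [Scenario(name=str(k), true_probs=tuple(v)) for k, v in payload.items()]
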