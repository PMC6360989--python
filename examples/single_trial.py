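"""Simulate one complete trial under each design on the same scenario.

Uses benchmark scenario 1 (true toxicity-by-6-months probabilities
0.05 ... 0.70 over six doses; the true MTD is dose 4 at 0.30) and
prints each design's declared MTD, sample size, toxicity count and
duration for a single random trial.
"""

from titedose import DESIGNS, TrialConfig, run_trial, scenario_table

config = TrialConfig()
scenario = scenario_table()[0]
print(f"scenario {scenario.name}: true probs {scenario.true_probs}, "
      f"true MTD dose {scenario.true_mtd(config.target)}\n")

print(f"{'design':>8} {'MTD':>4} {'n':>4} {'tox':>4} {'years':>6}")
for design in DESIGNS:
    res = run_trial(design, scenario, config, rng=42)
    print(f"{design:>8} {res.mtd_index:>4} {res.n_enrolled:>4} "
          f"{res.n_toxicities:>4} {res.duration_years:>6.2f}")

print(
    "\nThe time-to-event design treats patients the moment they arrive,\n"
    "so its duration is just enrollment plus one follow-up window\n"
    "(~1.5 years here), while the cohort designs wait out a 6-month\n"
    "evaluation between cohorts (~4 years without early stopping)."
)
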