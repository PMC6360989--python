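"""Small operating-characteristics study: two designs, two scenarios.

Runs 500 replicates per cell (a few seconds; the package's full studies
use 10,000) and prints the OC table plus the aggregate contrasts of the
time-to-event design against the 3+3.
"""

from titedose import TrialConfig, compare_designs, scenario_table

config = TrialConfig()
scenarios = [scenario_table()[0], scenario_table()[4]]

result = compare_designs(scenarios, ["TITE-IR", "3+3"], config, n_reps=500, seed=7)

cols = ["scenario", "design", "pcd", "mean_ntox", "mean_n",
        "mean_duration_years", "alloc_below", "alloc_at", "alloc_above"]
print(result.oc_table[cols].round(1).to_string(index=False))

print("\nper-dose selection percentages:")
print(result.selection.round(1).to_string(index=False))

adv = result.pcd_advantage["3+3"]
save = result.duration_saving["3+3"]
print(
    f"\nAveraged over these scenarios the time-to-event design selects the\n"
    f"true MTD {adv:+.1f} percentage points vs the 3+3 and finishes "
    f"{save:.1f} years sooner.\n"
    "PCD = % of replicates declaring the true MTD; alloc_* = % of patients\n"
    "treated below/at/above it."
)
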