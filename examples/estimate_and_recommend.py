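"""Estimate per-dose toxicity from partial follow-up and recommend the
next dose for an ongoing trial.

Builds a small mid-trial roster by hand: three patients at dose 1 (one
with an observed toxicity) and one fresh patient at dose 2, evaluated
six months into the trial, then prints the raw and isotonic estimates
and the conduct recommendation.
"""

from titedose import PatientRecord, TrialConfig, tite_next_dose

config = TrialConfig()  # 6 doses, target 1/3, tau = 6 months, F* = 0.05

roster = [
    # index, arrival, dose, toxicity, toxicity_time, follow-up at decision
    PatientRecord(1, 0.0, 1, 1, 2.0, 6.0, treatment_time=0.0),
    PatientRecord(2, 3.0, 1, 0, None, 3.0, treatment_time=3.0),
    PatientRecord(3, 0.5, 1, 0, None, 5.5, treatment_time=0.5),
    PatientRecord(4, 5.0, 2, 0, None, 1.0, treatment_time=5.0),
]

decision, summaries = tite_next_dose(roster, config)

print("dose   n  tox    qhat    phat")
for s in summaries:
    print(f"{s.dose_index:>4} {s.n:>3} {s.y:>4}  {s.qhat:.4f}  {s.phat:.4f}")
flag = " (constrained by a safety rule)" if decision.constrained else ""
print(f"\nnext patient -> dose {decision.dose_index}{flag}")
print(
    "\nqhat mixes observed toxicities (count 1 each) with partial\n"
    "follow-up credit (tau - t)/tau * (target + F*) for event-free\n"
    "patients; phat is its isotonic (non-decreasing) smoothing. The\n"
    "recommendation treats at the dose with phat closest to the target,\n"
    "subject to the escalation safety rules."
)
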