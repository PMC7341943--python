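"""Detect and classify branch events in a growing rhizoid system.

Branch events are found by comparing consecutive hourly frames; each is
classified apical (formed at the tip, parallel to the filament axis) or
lateral (inserted distal to the tip, starting a new axis).  In live cells
lateral branching dominates; the simulator reproduces this and its
ground-truth event log lets us verify the detector.
"""

from rhizomorph.branching import branch_ratio, detect_branch_events
from rhizomorph.simulator import preset, simulate

params = preset("replete")
params.seed = 4
series, log = simulate(params)

events = detect_branch_events(series, d_tip=1.0, theta_par=30.0)
lateral_frac, apical_frac, counts = branch_ratio(events)

true_lateral = sum(e.kind == "branch_lateral" for e in log)
print(f"ground truth : {len(log)} events, {true_lateral} lateral")
print(f"detected     : {len(events)} events")
print(f"classified   : {counts['lateral']} lateral / {counts['apical']} apical")
print(f"lateral fraction {lateral_frac:.2f} (simulator lateral probability 0.85)")
print()
print("Lateral dominance is the signature branching mode of rhizoids,")
print("as it is of hyphal fungi under apical dominance.")
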