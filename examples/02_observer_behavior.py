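"""Simulate the three observer models through one session and score them.

The tagged observer stores items with their task role (hits > distractor
false alarms), the untagged observer stores locations without roles
(hits = distractor false alarms), and the guessing observer answers from
bias alone.

Run:  python examples/02_observer_behavior.py
"""

import numpy as np

from cfswm import build_design, build_schedule, run_session
from cfswm import guessing_observer, tagged_observer, untagged_observer
from cfswm.behavior_stats import apply_exclusions, compute_rates
from cfswm.design import NONCONSCIOUS, StaircaseState

design = build_design(1)
schedule = build_schedule(design, seed=42)

for name, params in [
    ("tagged", tagged_observer()),
    ("untagged", untagged_observer()),
    ("guessing", guessing_observer()),
]:
    staircase = StaircaseState(current_rgb=design.staircase.start)
    records = run_session(schedule, params, staircase, seed=42,
                          staircase_config=design.staircase)
    retained, log = apply_exclusions(records)
    rates = compute_rates(retained, n_excluded=len(log))
    cell = rates.cell(NONCONSCIOUS, True)
    print(f"{name:9s}  nonconscious hit={cell.hit_rate:5.1f}%  "
          f"FA(distractor)={cell.fa_distractor_rate:5.1f}%  "
          f"guess={rates.yes_absent_rate:5.1f}%  "
          f"excluded={len(log)} trials  final contrast RGB={staircase.current_rgb}")
# Hit and false-alarm rates separate the observers: only the tagged observer
# shows hits above both the distractor false-alarm rate and the guessing rate.
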