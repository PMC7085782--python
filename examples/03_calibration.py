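"""The four-step per-subject calibration.

Threshold from a rest recording, maximal ATC from repeated movements, AROM
from the angle trace, and the stimulation current limit from the simulated
limb's response — everything the controller needs in one profile.
"""

import numpy as np

from atcfes import (
    calibrate_atc_max,
    calibrate_current_limit,
    calibrate_threshold,
    condition_signal,
    count_atc,
    detect_tc_events,
    evaluate_arom,
    linear_plant,
    make_activation_profile,
    synthesize_semg,
    therapist_angle,
)

# 1) threshold: step-down sweep on a rest recording
rest_env = make_activation_profile(1, 1.0, 2.0)
rest_env = type(rest_env)(t=rest_env.t, a=np.zeros_like(rest_env.a))
rest = condition_signal(synthesize_semg(rest_env, seed=2))
threshold = calibrate_threshold(rest)
print(f"1) threshold: {threshold:.0f} mV (detected baseline + 30 mV)")

# 2) maximal ATC: median of per-repetition maxima over 4 repetitions
cal_env = make_activation_profile(4, 4.0, 3.0)
sig = condition_signal(synthesize_semg(cal_env, seed=3))
events = detect_tc_events(sig, threshold)
reps = [count_atc(events, t0=3.0 + 7.0 * k - 0.5, t1=3.0 + 7.0 * (k + 1))
        for k in range(4)]
atc_max = calibrate_atc_max(reps)
print(f"2) maximal ATC: {atc_max} events/window "
      f"(per-rep maxima {[int(r.counts.max()) for r in reps]})")

# 3) AROM from the goniometer trace
angle = therapist_angle(cal_env, arom_deg=60.0)
arom = evaluate_arom(angle)
print(f"3) AROM: {arom:.2f} deg")

# 4) current limit: 110% of the current giving a 30% AROM change
plant = linear_plant(gain_deg_per_ma=2.0, arom_deg=60.0)
i_max = calibrate_current_limit(plant, arom)
print(f"4) current limit: {i_max:.2f} mA "
      f"(1.1 x the grid current reaching {0.3*arom:.1f} deg)")
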