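"""Generate the synthetic inputs the control method consumes.

Builds a 3-repetition trapezoidal activation protocol, modulates
band-limited noise with it to get a surrogate raw sEMG trace, and derives
the matching goniometer-style joint angle.
"""

import numpy as np

from atcfes import make_activation_profile, synthesize_semg, therapist_angle

env = make_activation_profile(n_reps=3, rep_duration_s=4.0, rest_s=3.0)
semg = synthesize_semg(env, seed=1)
angle = therapist_angle(env, arom_deg=60.0)

print(f"activation: {env.duration_s:.1f} s at {env.fs:.0f} Hz, "
      f"peak {env.a.max():.2f}")
print(f"raw sEMG:   {semg.duration_s:.1f} s at {semg.fs:.0f} Hz, "
      f"rest RMS {semg.v[:2000].std()*1000:.1f} uV, "
      f"active RMS {semg.v[np.interp(semg.t, env.t, env.a) > 0.9].std():.2f} mV")
print(f"angle:      peak {angle.theta.max():.2f} deg on the 12-bit grid "
      f"(step {360/4096:.3f} deg)")
# The sEMG amplitude tracks the activation envelope; the angle is a smoothed,
# quantized copy of it scaled to the 60 deg range of motion.
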