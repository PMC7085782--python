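"""The lookup-table controller and the biphasic pulse it commands.

Feeds a count stream through the 4-deep ATC matrix, takes the moving row
median, looks up the stimulation amplitude (first two levels are the noise
gateway), and renders one period of the commanded pulse.
"""

import numpy as np

from atcfes import (
    ControlState,
    build_current_matrix,
    build_fes_command,
    lookup_currents,
    median_index,
    synthesize_pulse_waveform,
    update_control,
)

lut = build_current_matrix(atc_max=10, i_max_ma=20.0)
print(f"LUT levels (mA): {[round(v, 1) for v in lut.levels_ma[0]]}")

state = ControlState.zeros(1)
stream = [0, 1, 0, 5, 6, 6, 7, 8, 1, 0, 0, 0]
print("count -> median index -> amplitude:")
for c in stream:
    state = update_control(state, [c])
    idx = median_index(state, lut)
    amp = lookup_currents(lut, idx)
    print(f"  {c:2d} -> {idx[0]:2d} -> {amp[0]:5.1f} mA")

cmd = build_fes_command([12.0])
wave = synthesize_pulse_waveform(cmd, fs=1e6, duration_s=1 / cmd.frequency_hz)
gap_us = ((np.flatnonzero(wave < 0)[0] - np.flatnonzero(wave > 0)[-1] - 1))
print(f"pulse: +{cmd.amplitudes_ma[0]:.0f} mA / {cmd.phase_width_us:.0f} us, "
      f"gap {gap_us:.0f} us, net charge {wave.sum():.1e} "
      f"(biphasic, charge-balanced)")
# Isolated counts vanish in the median (noise gateway); sustained counts
# ramp the amplitude, and it falls back to zero after the burst.
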