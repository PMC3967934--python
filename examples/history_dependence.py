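"""History dependence: gap recovery across stimulation cycles and post-pulse pauses.

Five 2-s cycles of 4 nA separated by a silent gap: with short gaps, Cycle 5
inherits the adaptation accumulated in earlier cycles (second-to-last-ISI
ratio Cycle5/Cycle1 below 1); longer gaps let the memory trace decay and the
ratio approaches 1.  Separately, at alpha = 0.1 a strong 2-s pulse on a 4 nA
baseline leaves a silent pause after the pulse ends that grows with pulse
amplitude and saturates, because the in-pulse firing rate is capped by the
refractory period.
"""

import numpy as np

from flif.params import experiment_matched_params, table1_params
from flif.protocols import pause_vs_pulse_amplitude, smallest_recovered_gap

gaps = np.array([100.0, 500.0, 1500.0, 3000.0, 6000.0, 12_000.0])
found, ratios = smallest_recovered_gap(table1_params(0.2), gaps, cycle_duration=2000.0, dt=0.5)
for g, r in ratios.items():
    print(f"gap {g / 1000:g} s: Cycle5/Cycle1 second-to-last-ISI ratio {r:.3f}")
print(f"first gap within 5% of full recovery: "
      f"{'none in sweep' if found is None else f'{found / 1000:g} s'}")

pauses = pause_vs_pulse_amplitude(params=experiment_matched_params(0.1))
for amp, pause in pauses.items():
    print(f"pulse {amp:g} nA -> pause {pause:.0f} ms")
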