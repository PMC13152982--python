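"""Simulate a pulsatile ZTE acquisition and self-gate respiration from k-space.

Builds the desk-scale digital phantom, samples the 3D radial k-space along
the spoke table, extracts the center-phase respiratory surrogate, and
compares the detected breathing rate against the generator's ground truth.
"""

import numpy as np

from ztepulse import AcquisitionConfig, respiratory_events_from_kspace, \
    simulate_run

config = AcquisitionConfig.desk_scale(matrix_size=16, readout_samples=10,
                                      n_volumes=250, spokes_per_volume=200)
print(f"acquisition: {config.duration:.1f} s, "
      f"{config.n_spokes_total} spokes, {config.matrix_size}^3 matrix")

bundle = simulate_run(config, seed=9)
events = respiratory_events_from_kspace(bundle["kspace"], bundle["spokes"])

truth = bundle["physio"].resp_peak_times
truth = truth[truth <= config.duration]
det_rate = 60.0 / np.mean(np.diff(events.event_times))
true_rate = 60.0 / np.mean(np.diff(truth))

print(f"true breathing rate      : {true_rate:.2f} /min")
print(f"self-gated breathing rate: {det_rate:.2f} /min "
      f"({100 * abs(det_rate - true_rate) / true_rate:.2f}% error)")
print("The surrogate is the phase of the first post-gap k-space sample per")
print("spoke; agreement within ~1% shows the k-space center tracks breathing.")
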