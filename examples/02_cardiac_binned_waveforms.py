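"""ECG-gated 40-bin cardiac reconstruction and arterial pulsation waveforms.

Runs the full chain — ECG artifact removal, R-peak detection, fractional
20-bin binning over two interleaved cycle populations, gated NUFFT/FISTA
reconstruction — and prints per-ROI peak amplitudes and peak times.
"""

import numpy as np

from ztepulse import AcquisitionConfig, peak_metrics
from ztepulse.pipeline import run_subject

config = AcquisitionConfig.desk_scale(matrix_size=16, readout_samples=10,
                                      n_volumes=100, spokes_per_volume=200)
res = run_subject(config=config, seed=3, do_resp=False)

asg = res["cardiac_assignment"]
print(f"{asg.n_cycles} cardiac cycles, mean bin duration "
      f"{asg.mean_bin_duration * 1e3:.2f} ms, 40 output bins")

for name, wf in res["cardiac_waveforms"].items():
    stats = peak_metrics(wf)
    print(f"{name:14s} amplitude {stats.peak_amplitude:5.2f}%  "
          f"peak at bin {stats.peak_bin % 20:2d} "
          f"({(stats.peak_bin % 20) * asg.mean_bin_duration * 1e3:.1f} ms "
          f"after the R-peak)")

print()
print("The early artery (cycle delay 0.15) peaks before the late artery")
print("(0.35): the phantom's stand-in for pulse-wave propagation from the")
print("internal carotid toward the pterygopalatine artery.")
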