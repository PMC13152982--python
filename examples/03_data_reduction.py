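"""Data-reduction robustness: how little data still shows arterial pulsation.

Rebins and reconstructs the cardiac-gated series from progressively shorter
initial segments of the acquisition and correlates each arterial waveform
with the full-data one.
"""

from ztepulse import AcquisitionConfig
from ztepulse.pipeline import run_subject
from ztepulse.pulsation import reduction_robustness

config = AcquisitionConfig.desk_scale(matrix_size=16, readout_samples=10,
                                      n_volumes=160, spokes_per_volume=200)
res = run_subject(config=config, seed=1, do_resp=False)

table = reduction_robustness(
    res["bundle"]["kspace"], res["bundle"]["spokes"],
    res["cardiac_assignment"],
    {"artery_early": res["roi_masks"]["artery_early"]},
    config, fractions=(1.0, 0.5, 0.25, 0.125))

print(table.to_string(index=False))
print()
print("r is the Pearson correlation of the reduced-data arterial waveform")
print("with the full-acquisition waveform; values above 0.5 at 1/8 of the")
print("data mean pulsations remain detectable from an eightfold-shorter scan.")
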