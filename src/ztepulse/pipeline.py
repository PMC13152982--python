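"""End-to-end orchestration: simulate -> gate -> bin -> reconstruct -> analyze.

These helpers chain the stage modules for one subject; the CLI, the
condition-comparison experiment and the examples are thin layers over them.
"""

from __future__ import annotations

import logging

import numpy as np

from . import binning, ecg, selfgate
from .connectivity import ConnectivityConfig, sliding_window_connectivity
from .geometry import AcquisitionConfig
from .pulsation import roi_waveform
from .recon import ReconConfig, reconstruct_series
from .simulate import PhantomSpec, default_phantom, simulate_run

log = logging.getLogger(__name__)


def cardiac_events_from_ecg(bundle: dict) -> ecg.CycleEvents:
    """ECG chain: onset refinement -> artifact regression -> R-peak detection."""
    rec = bundle["ecg"]
    onsets = ecg.refine_volume_onsets(rec)
    cleaned = ecg.remove_gradient_artifact(rec, onsets)
    events = ecg.detect_r_peaks(cleaned)
    return ecg.map_events_to_spokes(events, bundle["spokes"])


def gated_series(bundle: dict, events: ecg.CycleEvents,
                 gating: binning.GatingConfig, recon: ReconConfig, mode: str):
    cycles = binning.segment_cycles(events, gating)
    assignment = binning.assign_bins(bundle["spokes"], cycles, gating)
    series = reconstruct_series(bundle["kspace"], bundle["spokes"], assignment,
                                bundle["config"], recon, mode=mode)
    return series, assignment


def run_subject(config: AcquisitionConfig | None = None,
                phantom: PhantomSpec | None = None,
                heart_rate: float = 342.1, hr_jitter_cv: float = 0.022,
                resp_rate: float = 47.3, resp_jitter_cv: float = 0.076,
                artifact_amplitude: float = 5.0, seed: int = 0,
                gating: binning.GatingConfig = binning.GatingConfig(),
                recon: ReconConfig = ReconConfig(),
                rois: list | None = None,
                do_resp: bool = True,
                connectivity: ConnectivityConfig | None = None,
                fluct_band: tuple = (0.01, 0.1),
                subject: str = "", condition: str = "") -> dict:
    """Simulate and fully process one subject.

    Returns a dict with the simulation bundle, detected events, gated series
    and per-ROI waveforms; when a connectivity config is given, the standard
    series is reconstructed and sliding-window connectivity computed on the
    compartment ROI time series.
    """
    if config is None:
        config = AcquisitionConfig.desk_scale()
    if phantom is None:
        phantom = default_phantom(config)
    bundle = simulate_run(config, phantom, heart_rate=heart_rate,
                          hr_jitter_cv=hr_jitter_cv, resp_rate=resp_rate,
                          resp_jitter_cv=resp_jitter_cv,
                          artifact_amplitude=artifact_amplitude, seed=seed,
                          fluct_band=fluct_band)
    roi_names = rois or [c.name for c in phantom.compartments]
    masks = {name: phantom.roi_mask(name, config) for name in roi_names}

    out = dict(bundle=bundle, roi_masks=masks)

    card_events = cardiac_events_from_ecg(bundle)
    card_series, card_assignment = gated_series(bundle, card_events, gating,
                                                recon, "cardiac_gated")
    out.update(cardiac_events=card_events, cardiac_series=card_series,
               cardiac_assignment=card_assignment,
               cardiac_waveforms={n: roi_waveform(card_series, m, roi=n,
                                                  subject=subject,
                                                  condition=condition)
                                  for n, m in masks.items()})

    if do_resp:
        resp_events = selfgate.respiratory_events_from_kspace(
            bundle["kspace"], bundle["spokes"])
        resp_series, resp_assignment = gated_series(bundle, resp_events, gating,
                                                    recon, "resp_gated")
        out.update(resp_events=resp_events, resp_series=resp_series,
                   resp_assignment=resp_assignment,
                   resp_waveforms={n: roi_waveform(resp_series, m, roi=n,
                                                   subject=subject,
                                                   condition=condition)
                                   for n, m in masks.items()})
    else:
        out.update(resp_waveforms={})

    if connectivity is not None:
        std = reconstruct_series(bundle["kspace"], bundle["spokes"], None,
                                 config, recon, mode="standard")
        ts = np.column_stack([std.data[m].mean(axis=0)
                              for m in masks.values()])
        out["standard_series"] = std
        out["connectivity"] = sliding_window_connectivity(
            ts, connectivity, roi_names=list(masks))
    return out


def reduced_data_waveform_correlation(seed: int = 1,
                                      config: AcquisitionConfig | None = None,
                                      fraction: float = 1 / 8,
                                      roi: str = "artery_early") -> dict:
    """Pearson correlation between reduced-data and full-data ROI waveforms.

    Runs the full pipeline (simulation, ECG gating, 20-bin cardiac binning,
    gated reconstruction) at the desk-scale default, restricts the binning to
    the initial ``fraction`` of acquired volumes, reconstructs again, and
    correlates the two arterial waveforms over bins — the data-reduction
    robustness experiment in miniature.
    """
    from .binning import reduce_dataset
    if config is None:
        config = AcquisitionConfig.desk_scale()
    res = run_subject(config=config, seed=seed, do_resp=False)
    full_wf = res["cardiac_waveforms"][roi].values
    reduced = reduce_dataset(res["cardiac_assignment"],
                             res["bundle"]["spokes"], fraction)
    series = reconstruct_series(res["bundle"]["kspace"],
                                res["bundle"]["spokes"], reduced, config,
                                mode="cardiac_gated")
    red_wf = roi_waveform(series, res["roi_masks"][roi]).values
    r = float(np.corrcoef(full_wf, red_wf)[0, 1])
    return dict(r=r, full=full_wf, reduced=red_wf, result=res)
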