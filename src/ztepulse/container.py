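"""HDF5 run container and NIfTI/CSV export.

Mixed k-space / event / surrogate data has no community standard container;
one HDF5 file per run holds everything, with NIfTI-1 used where a standard
exists (image volumes, ROI label masks) and CSV for tidy tables.  All
datasets round-trip losslessly; a version attribute is checked on read.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .binning import BinAssignment
from .ecg import CycleEvents
from .geometry import AcquisitionConfig, SpokeTable
from .recon import VolumeSeries
from .selfgate import SurrogateSeries
from .simulate import ECGRecording, KSpaceData, PhysioTrace

log = logging.getLogger(__name__)

CONTAINER_VERSION = "1"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One JSON-serializable document reproducing an entire pipeline run.

    Every product of the pipeline is a function of this object plus the
    seed; no hidden state.
    """

    acquisition: "AcquisitionConfig" = None
    gating: "GatingConfig" = None
    recon: "ReconConfig" = None
    connectivity: "ConnectivityConfig" = None
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        from .connectivity import ConnectivityConfig
        from .recon import ReconConfig
        from .binning import GatingConfig
        if self.acquisition is None:
            object.__setattr__(self, "acquisition", AcquisitionConfig())
        if self.gating is None:
            object.__setattr__(self, "gating", GatingConfig())
        if self.recon is None:
            object.__setattr__(self, "recon", ReconConfig())
        if self.connectivity is None:
            object.__setattr__(self, "connectivity", ConnectivityConfig())

    def to_json(self) -> str:
        return json.dumps({
            "acquisition": dataclasses.asdict(self.acquisition),
            "gating": dataclasses.asdict(self.gating),
            "recon": dataclasses.asdict(self.recon),
            "connectivity": dataclasses.asdict(self.connectivity),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        from .connectivity import ConnectivityConfig
        from .recon import ReconConfig
        from .binning import GatingConfig
        data = json.loads(text)
        sections = {"acquisition": AcquisitionConfig, "gating": GatingConfig,
                    "recon": ReconConfig, "connectivity": ConnectivityConfig}
        unknown = set(data) - set(sections) - {"seed", "output_dir"}
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kw = {}
        for name, klass in sections.items():
            if name in data:
                known = {f.name for f in dataclasses.fields(klass)}
                extra = set(data[name]) - known
                if extra:
                    raise ValueError(
                        f"unknown {name} keys: {sorted(extra)}")
                kw[name] = klass(**data[name])
        return cls(seed=data.get("seed", 0),
                   output_dir=data.get("output_dir", "."), **kw)


def config_to_json(config: AcquisitionConfig) -> str:
    return json.dumps(dataclasses.asdict(config))


def config_from_json(text: str) -> AcquisitionConfig:
    data = json.loads(text)
    known = {f.name for f in dataclasses.fields(AcquisitionConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown AcquisitionConfig keys: {sorted(unknown)}")
    return AcquisitionConfig(**data)


def write_container(path, bundle: dict) -> None:
    """Write a run bundle (any subset of the known keys) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = CONTAINER_VERSION
        cfg = bundle.get("config")
        if cfg is not None:
            f.attrs["acquisition_config"] = config_to_json(cfg)
        sp: SpokeTable | None = bundle.get("spokes")
        if sp is not None:
            g = f.create_group("spokes")
            g.create_dataset("directions", data=sp.directions)
            g.create_dataset("timestamps", data=sp.timestamps)
            g.create_dataset("volume_index", data=sp.volume_index)
        ks: KSpaceData | None = bundle.get("kspace")
        if ks is not None:
            g = f.create_group("kspace")
            g.create_dataset("samples", data=ks.samples)
            g.create_dataset("radii", data=ks.radii)
            g.attrs["gap"] = ks.gap
        ecg: ECGRecording | None = bundle.get("ecg")
        if ecg is not None:
            g = f.create_group("ecg")
            g.create_dataset("signal", data=ecg.signal)
            g.create_dataset("trigger_times", data=ecg.trigger_times)
            g.attrs["sampling_rate"] = ecg.sampling_rate
        phy: PhysioTrace | None = bundle.get("physio")
        if phy is not None:
            g = f.create_group("truth")
            g.create_dataset("r_peak_times", data=phy.r_peak_times)
            g.create_dataset("resp_peak_times", data=phy.resp_peak_times)
        for key in ("cardiac_events", "resp_events"):
            ev: CycleEvents | None = bundle.get(key)
            if ev is not None:
                g = f.create_group(key)
                g.create_dataset("event_times", data=ev.event_times)
                g.attrs["source"] = ev.source
                if ev.event_spoke is not None:
                    g.create_dataset("event_spoke", data=ev.event_spoke)
                    g.create_dataset("event_volume", data=ev.event_volume)
        sur: SurrogateSeries | None = bundle.get("surrogate")
        if sur is not None:
            g = f.create_group("surrogate")
            g.create_dataset("value", data=sur.value)
            g.create_dataset("timestamps", data=sur.timestamps)
            g.attrs["stage"] = sur.stage
        asg: BinAssignment | None = bundle.get("assignment")
        if asg is not None:
            g = f.create_group("assignment")
            g.create_dataset("bin_index", data=asg.bin_index)
            g.attrs["n_output_bins"] = asg.n_output_bins
            g.attrs["mean_bin_duration"] = asg.mean_bin_duration
            g.attrs["n_cycles"] = asg.n_cycles


def read_container(path) -> dict:
    """Read a run container back into the in-memory bundle representation."""
    out: dict = {}
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable HDF5 container: {path}") from exc
    with f:
        version = f.attrs.get("version")
        if version != CONTAINER_VERSION:
            raise ValueError(
                f"container version mismatch: got {version!r}, "
                f"expected {CONTAINER_VERSION!r}")
        if "acquisition_config" in f.attrs:
            out["config"] = config_from_json(f.attrs["acquisition_config"])
        if "spokes" in f:
            g = f["spokes"]
            vol = g["volume_index"][()]
            cfg = out.get("config")
            spv = (cfg.spokes_per_volume if cfg is not None
                   else int(np.sum(vol == 0)))
            n = vol.size
            out["spokes"] = SpokeTable(
                directions=g["directions"][()], timestamps=g["timestamps"][()],
                volume_index=vol, spoke_in_volume=np.arange(n) % spv,
                direction_id=np.arange(n) % spv, config=cfg)
        if "kspace" in f:
            g = f["kspace"]
            out["kspace"] = KSpaceData(samples=g["samples"][()],
                                       gap=int(g.attrs["gap"]),
                                       radii=g["radii"][()],
                                       config=out.get("config"))
        if "ecg" in f:
            g = f["ecg"]
            out["ecg"] = ECGRecording(signal=g["signal"][()],
                                      sampling_rate=float(g.attrs["sampling_rate"]),
                                      trigger_times=g["trigger_times"][()])
        if "truth" in f:
            g = f["truth"]
            out["physio"] = PhysioTrace(r_peak_times=g["r_peak_times"][()],
                                        resp_peak_times=g["resp_peak_times"][()])
        for key in ("cardiac_events", "resp_events"):
            if key in f:
                g = f[key]
                out[key] = CycleEvents(
                    event_times=g["event_times"][()],
                    source=str(g.attrs["source"]),
                    event_spoke=g["event_spoke"][()] if "event_spoke" in g else None,
                    event_volume=g["event_volume"][()] if "event_volume" in g else None)
        if "surrogate" in f:
            g = f["surrogate"]
            out["surrogate"] = SurrogateSeries(value=g["value"][()],
                                               timestamps=g["timestamps"][()],
                                               stage=str(g.attrs["stage"]))
        if "assignment" in f:
            g = f["assignment"]
            out["assignment"] = BinAssignment(
                bin_index=g["bin_index"][()],
                n_output_bins=int(g.attrs["n_output_bins"]),
                mean_bin_duration=float(g.attrs["mean_bin_duration"]),
                n_cycles=int(g.attrs["n_cycles"]))
    return out


def series_to_nifti(series: VolumeSeries, path) -> None:
    """Write a VolumeSeries as 4D NIfTI-1 (RAS, mm voxels, frame duration)."""
    affine = np.diag([series.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header["pixdim"][4] = series.frame_duration
    img.header.set_xyzt_units("mm", "sec")
    img.header["descrip"] = series.mode.encode()[:79]
    nib.save(img, str(path))


def labels_to_nifti(labels: np.ndarray, voxel_size: float, path) -> None:
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def events_to_csv(events: CycleEvents, path) -> None:
    pd.DataFrame({
        "time_s": events.event_times,
        "spoke": events.event_spoke if events.event_spoke is not None else -1,
        "volume": events.event_volume if events.event_volume is not None else -1,
    }).to_csv(path, index=False)


def surrogate_to_csv(sur: SurrogateSeries, path) -> None:
    pd.DataFrame({"spoke": np.arange(sur.value.size),
                  "time_s": sur.timestamps,
                  "value": sur.value}).to_csv(path, index=False)


def waveforms_to_csv(waveforms: dict, path) -> None:
    rows = []
    for name, wf in waveforms.items():
        for b, v in enumerate(wf.values):
            rows.append(dict(subject=wf.subject, condition=wf.condition,
                             roi=name, bin=b, value=v,
                             bin_duration_s=wf.bin_duration))
    pd.DataFrame(rows).to_csv(path, index=False)
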