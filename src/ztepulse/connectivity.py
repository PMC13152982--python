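"""Sliding-window functional connectivity and two-condition statistics.

The standard (ungated) reconstruction retains slow signal fluctuations;
pairwise ROI Pearson correlations are computed in overlapping temporal
windows (defaults 250 volumes, 125-volume step) and averaged over windows.
Condition comparisons use two-sided paired t-tests with Benjamini-Hochberg
FDR correction across ROI pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityConfig:
    window_volumes: int = 250
    step_volumes: int = 125
    alpha: float = 0.05
    fisher_z: bool = False        # average r directly by default

    def __post_init__(self):
        if not 0 < self.step_volumes <= self.window_volumes:
            raise ValueError("need 0 < step <= window")


@dataclass
class ConnectivityResult:
    window_matrices: np.ndarray   # (n_windows, R, R), NaN where undefined
    mean_matrix: np.ndarray       # (R, R)
    roi_names: list

    @property
    def n_windows(self) -> int:
        return self.window_matrices.shape[0]


def window_count(frames: int, window: int, step: int) -> int:
    """Number of sliding windows: floor((frames - window)/step) + 1."""
    if window > frames:
        raise ValueError("window longer than the series")
    return (frames - window) // step + 1


def sliding_window_connectivity(roi_timeseries: np.ndarray,
                                config: ConnectivityConfig = ConnectivityConfig(),
                                roi_names: list | None = None) -> ConnectivityResult:
    """Per-window ROI-pair Pearson correlations and their mean.

    roi_timeseries: (frames, n_rois).  A zero-variance ROI within a window
    yields NaN for its pairs in that window; NaNs are excluded from the mean.
    """
    ts = np.asarray(roi_timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("roi_timeseries must be (frames, n_rois)")
    frames, nroi = ts.shape
    nw = window_count(frames, config.window_volumes, config.step_volumes)
    mats = np.empty((nw, nroi, nroi))
    for wi in range(nw):
        a = wi * config.step_volumes
        seg = ts[a:a + config.window_volumes]
        sd = seg.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg, rowvar=False)
        c = np.atleast_2d(c)
        bad = sd == 0
        c[bad, :] = np.nan
        c[:, bad] = np.nan
        np.fill_diagonal(c, 1.0)
        mats[wi] = c
    vals = np.arctanh(np.clip(mats, -1 + 1e-12, 1 - 1e-12)) if config.fisher_z else mats
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
    if config.fisher_z:
        mean = np.tanh(mean)
    np.fill_diagonal(mean, 1.0)
    names = roi_names or [f"roi{i}" for i in range(nroi)]
    return ConnectivityResult(window_matrices=mats, mean_matrix=mean,
                              roi_names=list(names))


def paired_ttest_fdr(values_a: np.ndarray, values_b: np.ndarray,
                     alpha: float = 0.05):
    """Two-sided paired t-tests per column with Benjamini-Hochberg correction.

    values_a/b: (n_subjects, n_measures) paired observations.  Zero-variance
    differences give p = 1 for that measure.  Returns (p, q, flags).
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired conditions must have equal shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired subjects")
    d = a - b
    p = np.empty(d.shape[1])
    for j in range(d.shape[1]):
        if np.allclose(d[:, j].std(ddof=1), 0.0):
            log.info("zero-variance paired differences in measure %d; p set to 1", j)
            p[j] = 1.0
        else:
            p[j] = sstats.ttest_rel(a[:, j], b[:, j]).pvalue
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    flags = q < alpha
    return p, q, flags


def upper_pairs(n: int):
    """Indices of the strict upper triangle, the ROI-pair ordering used here."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def condition_comparison_experiment(spec_a: dict, spec_b: dict,
                                    n_subjects: int = 8, seed: int = 0,
                                    alpha: float = 0.05,
                                    connectivity: ConnectivityConfig | None = None,
                                    **pipeline_kwargs) -> dict:
    """Synthetic paired two-condition experiment through the full pipeline.

    spec_a / spec_b are keyword overrides for :func:`ztepulse.pipeline.run_subject`
    (e.g. phantom with a different arterial cardiac amplitude, lower heart /
    breathing rates for condition B).  Each of ``n_subjects`` subjects is
    simulated and processed under both conditions with a subject-specific
    seed; per-ROI cardiac and respiratory peak amplitudes are compared with
    paired t-tests + FDR, and, when a connectivity configuration is given,
    mean sliding-window connectivity matrices are compared per ROI pair.
    """
    from .pipeline import run_subject

    if n_subjects < 3:
        raise ValueError("need at least 3 paired subjects")
    amp_rows = []
    conn = {"A": [], "B": []}
    roi_order = None
    for s in range(n_subjects):
        for label, spec in (("A", spec_a), ("B", spec_b)):
            kw = dict(pipeline_kwargs)
            kw.update(spec)
            res = run_subject(seed=seed + 1000 * s + (0 if label == "A" else 1),
                              subject=f"s{s}", condition=label,
                              connectivity=connectivity, **kw)
            for kind in ("cardiac", "resp"):
                for roi, wf in res[f"{kind}_waveforms"].items():
                    from .pulsation import peak_metrics
                    amp_rows.append(dict(subject=s, condition=label, kind=kind,
                                         roi=roi,
                                         amplitude=peak_metrics(wf).peak_amplitude))
            if connectivity is not None:
                conn[label].append(res["connectivity"].mean_matrix)
                roi_order = res["connectivity"].roi_names
    amps = pd.DataFrame(amp_rows)

    tests = {}
    for kind in ("cardiac", "resp"):
        sub = amps[amps.kind == kind]
        piv_a = sub[sub.condition == "A"].pivot(index="subject", columns="roi",
                                                values="amplitude")
        piv_b = sub[sub.condition == "B"].pivot(index="subject", columns="roi",
                                                values="amplitude")
        piv_b = piv_b[piv_a.columns]
        p, q, flags = paired_ttest_fdr(piv_a.values, piv_b.values, alpha=alpha)
        tests[kind] = pd.DataFrame(dict(roi=piv_a.columns, p=p, q=q,
                                        significant=flags))

    out = dict(amplitudes=amps, amplitude_tests=tests)
    if connectivity is not None:
        pairs = upper_pairs(len(roi_order))
        va = np.array([[m[i, j] for i, j in pairs] for m in conn["A"]])
        vb = np.array([[m[i, j] for i, j in pairs] for m in conn["B"]])
        p, q, flags = paired_ttest_fdr(va, vb, alpha=alpha)
        out["connectivity_tests"] = pd.DataFrame(
            dict(pair=[f"{roi_order[i]}-{roi_order[j]}" for i, j in pairs],
                 p=p, q=q, significant=flags))
        out["connectivity_mean"] = {k: np.mean(v, axis=0) for k, v in conn.items()}
        out["roi_names"] = roi_order
    return out
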