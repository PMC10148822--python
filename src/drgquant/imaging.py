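"""Stimulus-locked calcium-response quantification.

Implements the response-calling procedure for in vivo DRG GCaMP recordings:

* dF/F0 normalization against the mean of a force-free baseline block,
* responder calling: a neuron responds to a stimulus when its peak dF/F0
  during the application window strictly exceeds ``k`` (default 4) times the
  standard deviation of baseline dF/F0,
* peak area under the curve (AUC) of the response transient, integrated over
  the contiguous positive-dF/F0 run containing the peak,
* extrapolation of the total number of neurons imaged from a counted
  sub-region of average density,
* percent responders (# responses / # total neurons imaged x 100),
* relative-frequency distributions of responder soma areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .protocol import ImagingProtocol

__all__ = [
    "ImagingSession",
    "DffTrace",
    "ResponseCall",
    "SessionSummary",
    "extract_traces",
    "compute_dff",
    "call_response",
    "peak_auc",
    "estimate_total_neurons",
    "percent_responders",
    "area_histogram",
    "analyze_session",
    "summarize_session",
    "noise_false_positive_rate",
    "expected_false_positive_rate",
    "DEFAULT_AREA_BIN_EDGES",
]

#: Default soma-area histogram bins: 100 um^2 wide from 0 to 2000 um^2.
DEFAULT_AREA_BIN_EDGES = np.arange(0.0, 2100.0, 100.0)


@dataclass
class ImagingSession:
    """A framed fluorescence recording with protocol metadata.

    ``traces`` holds raw fluorescence (arbitrary units), one row per neuron,
    one column per frame; ``areas_um2`` is the soma area of each ROI.
    """

    protocol: ImagingProtocol
    traces: np.ndarray
    neuron_ids: np.ndarray
    areas_um2: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (neurons x frames) array")
        if self.traces.shape[1] != self.protocol.n_frames:
            raise ValueError(
                f"trace length {self.traces.shape[1]} != protocol frame "
                f"count {self.protocol.n_frames}"
            )
        n = self.traces.shape[0]
        if len(self.neuron_ids) != n or len(self.areas_um2) != n:
            raise ValueError("neuron_ids/areas_um2 must match trace count")
        if np.any(self.traces < 0):
            raise ValueError("fluorescence must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]


@dataclass
class DffTrace:
    """Per-neuron normalized trace: dF/F0 plus its baseline statistics."""

    neuron_id: object
    f0: float
    dff: np.ndarray
    baseline_sd: float


@dataclass
class ResponseCall:
    """Responder decision for one (neuron, stimulus) pair."""

    neuron_id: object
    stimulus: str
    peak_dff: float
    threshold: float
    responder: bool
    peak_auc: float = np.nan
    area_um2: float = np.nan


@dataclass
class SessionSummary:
    """Per-stimulus session summary plus responder-area distributions."""

    per_stimulus: pd.DataFrame
    area_histograms: dict[str, pd.DataFrame] = field(default_factory=dict)


# ----------------------------------------------------------------------------
# trace extraction from rendered stacks
# ----------------------------------------------------------------------------

def extract_traces(
    stack: np.ndarray, rois: np.ndarray, pixel_size_um: float = 1.92
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-ROI fluorescence traces and soma areas from a labelled stack.

    Parameters
    ----------
    stack
        ``(n_frames, h, w)`` image stack.
    rois
        ``(h, w)`` label image; positive integer labels mark ROIs, 0 is
        background.
    pixel_size_um
        Pixel edge length; ROI area is pixel count x pixel_size_um**2.

    Returns
    -------
    traces, labels, areas_um2
        ``traces[i]`` is the per-frame mean intensity inside ROI
        ``labels[i]``.
    """
    stack = np.asarray(stack, dtype=float)
    rois = np.asarray(rois)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames, height, width)")
    if rois.shape != stack.shape[1:]:
        raise ValueError("ROI label image does not match stack frame shape")
    labels = np.unique(rois)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("ROI label image contains no positive labels")
    flat = stack.reshape(stack.shape[0], -1)
    traces = np.empty((labels.size, stack.shape[0]))
    areas = np.empty(labels.size)
    rflat = rois.ravel()
    for i, lab in enumerate(labels):
        idx = np.flatnonzero(rflat == lab)
        traces[i] = flat[:, idx].mean(axis=1)
        areas[i] = idx.size * pixel_size_um**2
    return traces, labels, areas


# ----------------------------------------------------------------------------
# dF/F0 and responder calling
# ----------------------------------------------------------------------------

def compute_dff(
    trace: np.ndarray,
    baseline_frames: Sequence[int],
    neuron_id: object = None,
    ddof: int = 1,
) -> DffTrace:
    """Normalize a raw fluorescence trace to dF/F0.

    ``f0`` is the mean intensity over ``baseline_frames``;
    ``dff[t] = (trace[t] - f0) / f0``.  ``baseline_sd`` is the standard
    deviation of dF/F0 over the same baseline frames (sample SD, ``ddof=1``,
    by default).  Because dF/F0 is an affine function of raw fluorescence,
    thresholding k x SD of dF/F0 and k x SD of raw fluorescence yield the
    identical responder decision.
    """
    trace = np.asarray(trace, dtype=float)
    idx = np.asarray(list(baseline_frames), dtype=int)
    if idx.size == 0:
        raise ValueError("baseline_frames must be non-empty")
    if idx.min() < 0 or idx.max() >= trace.size:
        raise ValueError("baseline frame index out of range")
    f0 = float(trace[idx].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline mean F0={f0}; corrupt input")
    dff = (trace - f0) / f0
    sd = float(np.std(dff[idx], ddof=ddof)) if idx.size > ddof else 0.0
    return DffTrace(neuron_id=neuron_id, f0=f0, dff=dff, baseline_sd=sd)


#: Absolute floor on a detectable peak; guards the degenerate zero-SD case
#: (a noiseless baseline yields dF/F0 of ~1 ulp, which must not trip the
#: strict > comparison against a threshold of exactly 0).
PEAK_ATOL = 1e-12


def _is_responder(peak_dff: np.ndarray, baseline_sd: np.ndarray, k: float) -> np.ndarray:
    """The responder rule: peak dF/F0 strictly greater than k x baseline SD."""
    return np.asarray(peak_dff) > k * np.asarray(baseline_sd) + PEAK_ATOL


def call_response(
    dff: DffTrace, application_window: Sequence[int], k: float = 4.0, stimulus: str = ""
) -> ResponseCall:
    """Classify one neuron's response to one stimulus.

    The neuron is a responder iff its peak dF/F0 within the application
    window strictly exceeds ``k`` times the baseline SD ("greater than", so a
    peak exactly at threshold is a non-responder).
    """
    idx = np.asarray(list(application_window), dtype=int)
    if idx.size == 0:
        raise ValueError("application window is empty")
    if idx.min() < 0 or idx.max() >= dff.dff.size:
        raise ValueError("application window out of range")
    peak = float(dff.dff[idx].max())
    thr = k * dff.baseline_sd
    return ResponseCall(
        neuron_id=dff.neuron_id,
        stimulus=stimulus,
        peak_dff=peak,
        threshold=float(thr),
        responder=bool(_is_responder(peak, dff.baseline_sd, k)),
    )


def peak_auc(
    dff: DffTrace,
    application_window: Sequence[int],
    frame_rate: float,
    run_bounds: tuple[int, int] | None = None,
) -> float:
    """Area under the peak response transient, in dF/F0 x seconds.

    Locates the frame of maximal dF/F0 within the application window, expands
    to the maximal contiguous run of frames with dF/F0 > 0 containing that
    frame (the run may extend beyond the window, e.g. into post-stimulus
    frames), and integrates dF/F0 over the run with the trapezoidal rule at
    frame spacing ``1/frame_rate``.  ``run_bounds`` optionally clips the run
    to ``[lo, hi)`` frame indices (typically the epoch of the stimulus, so a
    run never bleeds into a neighbouring epoch).  A flat or non-positive peak
    returns 0.0.
    """
    idx = np.asarray(list(application_window), dtype=int)
    if idx.size == 0:
        raise ValueError("application window is empty")
    y = dff.dff
    peak_frame = int(idx[np.argmax(y[idx])])
    if y[peak_frame] <= 0:
        return 0.0
    lo_bound, hi_bound = (0, y.size) if run_bounds is None else run_bounds
    lo = peak_frame
    while lo - 1 >= lo_bound and y[lo - 1] > 0:
        lo -= 1
    hi = peak_frame
    while hi + 1 < hi_bound and y[hi + 1] > 0:
        hi += 1
    if hi == lo:
        return 0.0
    run = y[lo : hi + 1]
    return float(max(np.trapezoid(run, dx=1.0 / frame_rate), 0.0))


# ----------------------------------------------------------------------------
# session-level quantities
# ----------------------------------------------------------------------------

def estimate_total_neurons(
    count_in_subregion: int, subregion_area_um2: float, imaged_area_um2: float
) -> int:
    """Extrapolate a neuron count from a sub-region of average density.

    Returns ``round(count * imaged_area / subregion_area)`` with halves
    rounded away from zero.
    """
    if subregion_area_um2 <= 0 or imaged_area_um2 <= 0:
        raise ValueError("areas must be positive")
    if subregion_area_um2 > imaged_area_um2:
        raise ValueError("sub-region cannot exceed the imaged area")
    if count_in_subregion < 0:
        raise ValueError("count must be non-negative")
    x = count_in_subregion * imaged_area_um2 / subregion_area_um2
    return int(np.floor(x + 0.5))


def percent_responders(n_responses: int, total_neurons: int) -> float:
    """Percent of imaged neurons that responded: 100 x responses / total."""
    if total_neurons <= 0:
        raise ValueError("total_neurons must be positive")
    if not 0 <= n_responses <= total_neurons:
        raise ValueError("need 0 <= n_responses <= total_neurons")
    return 100.0 * n_responses / total_neurons


def area_histogram(
    areas_um2: Sequence[float],
    bin_edges: np.ndarray = DEFAULT_AREA_BIN_EDGES,
    include_out_of_range: bool = True,
) -> pd.DataFrame:
    """Relative-frequency distribution of responder soma areas.

    Returns a DataFrame with columns ``bin_left``, ``bin_right``, ``count``
    and ``frequency``; frequencies sum to 1 whenever any areas are given.
    With ``include_out_of_range`` (default) values beyond the outer edges are
    folded into the first/last bin, so no responder is dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    areas = np.asarray(list(areas_um2), dtype=float)
    if areas.size and np.any(areas <= 0):
        raise ValueError("areas must be positive")
    if include_out_of_range and areas.size:
        areas = np.clip(areas, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(areas, bins=edges)
    freq = counts / areas.size if areas.size else np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": freq,
        }
    )


def analyze_session(
    session: ImagingSession,
    k: float = 4.0,
    baseline_mode: str = "global",
    ddof: int = 1,
) -> pd.DataFrame:
    """Run dF/F0 normalization and responder calling over a whole session.

    Parameters
    ----------
    session
        The recording (traces + protocol + ROI areas).
    k
        Responder threshold multiplier (peak dF/F0 > k x baseline SD).
    baseline_mode
        ``"global"`` (default): F0 and the baseline SD come from the
        force-free global baseline block.  ``"prestim"``: both come from the
        10 pre-stimulus frames of each epoch instead.
    ddof
        Delta degrees of freedom of the baseline SD (1 = sample SD).

    Returns
    -------
    DataFrame with one row per (neuron, stimulus):
    neuron_id, stimulus, f0, baseline_sd, peak_dff, threshold, responder,
    peak_auc, area_um2.
    """
    if baseline_mode not in ("global", "prestim"):
        raise ValueError("baseline_mode must be 'global' or 'prestim'")
    proto = session.protocol
    rows = []
    for i in range(session.n_neurons):
        trace = session.traces[i]
        if baseline_mode == "global":
            d = compute_dff(trace, proto.global_baseline_frames,
                            neuron_id=session.neuron_ids[i], ddof=ddof)
        for stim in proto.stimulus_labels:
            if baseline_mode == "prestim":
                d = compute_dff(trace, proto.prestim_frames(stim),
                                neuron_id=session.neuron_ids[i], ddof=ddof)
            window = proto.application_frames(stim)
            call = call_response(d, window, k=k, stimulus=stim)
            epoch = proto.epoch_frames(stim)
            call.peak_auc = peak_auc(
                d, window, proto.frame_rate,
                run_bounds=(epoch.start, epoch.stop),
            )
            call.area_um2 = float(session.areas_um2[i])
            rows.append(
                {
                    "neuron_id": call.neuron_id,
                    "stimulus": stim,
                    "f0": d.f0,
                    "baseline_sd": d.baseline_sd,
                    "peak_dff": call.peak_dff,
                    "threshold": call.threshold,
                    "responder": call.responder,
                    "peak_auc": call.peak_auc,
                    "area_um2": call.area_um2,
                }
            )
    return pd.DataFrame(rows)


def summarize_session(
    calls: pd.DataFrame,
    total_neurons: int | dict[str, int] | None = None,
    bin_edges: np.ndarray = DEFAULT_AREA_BIN_EDGES,
) -> SessionSummary:
    """Aggregate per-neuron calls into per-stimulus session statistics.

    ``total_neurons`` is the (possibly density-extrapolated) total number of
    neurons imaged, either one integer for all stimuli or a per-stimulus
    mapping; when omitted, the number of analyzed neurons is used.  Mean peak
    AUC is averaged over responders only and reported as missing (NaN) when a
    stimulus has no responders.
    """
    rows = []
    hists: dict[str, pd.DataFrame] = {}
    for stim, grp in calls.groupby("stimulus", sort=False):
        n_resp = int(grp["responder"].sum())
        if isinstance(total_neurons, dict):
            total = int(total_neurons[stim])
        elif total_neurons is not None:
            total = int(total_neurons)
        else:
            total = int(grp["neuron_id"].nunique())
        responders = grp[grp["responder"]]
        mean_auc = float(responders["peak_auc"].mean()) if n_resp else np.nan
        rows.append(
            {
                "stimulus": stim,
                "n_responders": n_resp,
                "total_neurons": total,
                "percent_responders": percent_responders(n_resp, total),
                "mean_peak_auc": mean_auc,
            }
        )
        hists[stim] = area_histogram(responders["area_um2"].to_numpy(), bin_edges)
    return SessionSummary(per_stimulus=pd.DataFrame(rows), area_histograms=hists)


# ----------------------------------------------------------------------------
# specificity of the k-sigma rule on pure noise
# ----------------------------------------------------------------------------

def expected_false_positive_rate(k: float = 4.0, window_len: int = 10) -> float:
    """Analytic false-positive rate of the k-sigma rule on i.i.d. Gaussian noise.

    With dF/F0 pure noise ~ N(0, sigma^2) and the true sigma used as the
    baseline SD, the peak of ``window_len`` independent frames exceeds
    k*sigma with probability ``1 - Phi(k)**window_len``.
    """
    return float(1.0 - norm.cdf(k) ** window_len)


def noise_false_positive_rate(
    n_windows: int,
    window_len: int = 10,
    sigma: float = 1.0,
    k: float = 4.0,
    seed: int | None = None,
) -> float:
    """Monte-Carlo false-positive rate of the responder rule on pure noise.

    Simulates ``n_windows`` application windows of i.i.d. N(0, sigma^2)
    dF/F0 noise, supplies the true sigma as the baseline SD, and applies the
    same strict peak > k x SD decision used by :func:`call_response`.
    """
    if n_windows <= 0 or window_len <= 0:
        raise ValueError("n_windows and window_len must be positive")
    rng = np.random.default_rng(seed)
    fp = 0
    chunk = 200_000
    for start in range(0, n_windows, chunk):
        m = min(chunk, n_windows - start)
        peaks = rng.normal(0.0, sigma, size=(m, window_len)).max(axis=1)
        fp += int(_is_responder(peaks, sigma, k).sum())
    return fp / n_windows
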