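"""Synthetic stimulus-locked DRG calcium recordings with full ground truth.

Emulates a two-photon GCaMP6s acquisition: a force-free baseline block, then
per-stimulus epochs of pre / application / post frames at 0.7 Hz.  Each
neuron is either a responder (carries a calcium transient locked to the
stimulus) or a non-responder, with additive Gaussian acquisition noise
proportional to its baseline fluorescence and lognormal soma areas.

The transient amplitude is expressed in dF/F0 units: kernel samples are
normalized so the maximal *sampled* dF/F0 of a noiseless responder equals
the configured amplitude exactly.  The default kernel models the sustained
10-frame force application (saturating rise, plateau while the force is
held, exponential decay after release); an impulse kernel
(difference of exponentials) is available for brief events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..imaging import ImagingSession
from ..protocol import ImagingProtocol

__all__ = ["SimConfig", "NeuronGroundTruth", "generate_imaging_dataset", "render_stack"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic imaging session.

    ``responder_probability`` may be a single float (shared by all stimuli)
    or a mapping from stimulus label to probability.  Amplitudes are drawn
    from a lognormal (median ``exp(amplitude_mu)`` dF/F0, log-SD
    ``amplitude_sigma``) floored at ``amplitude_min``; areas from a
    lognormal in um^2.  ``noise_sd`` is the SD of the additive Gaussian
    noise as a fraction of each neuron's baseline fluorescence (so it is
    also the dF/F0 noise SD).
    """

    n_neurons: int = 300
    responder_probability: float | dict[str, float] = 0.1
    amplitude_mu: float = 0.0
    amplitude_sigma: float = 0.5
    amplitude_min: float = 0.2
    noise_sd: float = 0.02
    area_mu: float = 6.1
    area_sigma: float = 0.5
    baseline_mu: float = 5.0
    baseline_sigma: float = 0.3
    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.5
    kernel: str = "sustained"
    onset_jitter_frames: int = 3
    seed: int = 0
    output_mode: str = "traces"
    forbid_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        probs = (
            self.responder_probability.values()
            if isinstance(self.responder_probability, dict)
            else [self.responder_probability]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("responder_probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kernel not in ("sustained", "impulse"):
            raise ValueError("kernel must be 'sustained' or 'impulse'")
        if self.output_mode not in ("traces", "stack"):
            raise ValueError("output_mode must be 'traces' or 'stack'")
        if self.onset_jitter_frames < 1:
            raise ValueError("onset_jitter_frames must be >= 1")


@dataclass
class NeuronGroundTruth:
    """What the simulator actually put into one neuron's trace."""

    neuron_id: int
    centroid_um: tuple[float, float]
    area_um2: float
    baseline_fluorescence: float
    responder_flags: dict[str, bool]
    transient_amplitude: dict[str, float]
    transient_onset_frame: dict[str, int]
    rise_tau_s: float
    decay_tau_s: float


def _kernel_samples(
    config: SimConfig,
    protocol: ImagingProtocol,
    onset: int,
    stim_end: int,
    n_frames: int,
    epoch_end: int | None = None,
) -> np.ndarray:
    """Unit-peak kernel sampled on the frame grid, zero before onset.

    The transient is truncated at ``epoch_end``: the acquisition protocol
    rests the animal between stimuli until fluorescence returns to
    baseline, so no response bleeds into the next epoch.
    """
    dt = protocol.frame_interval_s
    t = (np.arange(n_frames) - onset) * dt
    y = np.zeros(n_frames)
    if config.kernel == "sustained":
        # rise toward 1 while the force is held, exponential decay after
        hold = (t >= 0) & (np.arange(n_frames) < stim_end)
        y[hold] = 1.0 - np.exp(-t[hold] / config.rise_tau_s)
        after = np.arange(n_frames) >= stim_end
        t_rel = (stim_end - onset) * dt
        level = 1.0 - np.exp(-t_rel / config.rise_tau_s)
        y[after] = level * np.exp(-(t[after] - t_rel) / config.decay_tau_s)
    else:  # impulse: difference of exponentials
        pos = t >= 0
        y[pos] = np.exp(-t[pos] / config.decay_tau_s) - np.exp(
            -t[pos] / config.rise_tau_s
        )
    if epoch_end is not None:
        y[epoch_end:] = 0.0
    peak = y.max()
    if peak > 0:
        y /= peak
    return y


def generate_imaging_dataset(
    config: SimConfig, protocol: ImagingProtocol | None = None
) -> tuple[ImagingSession, list[NeuronGroundTruth]]:
    """Simulate one imaging session plus its per-neuron ground truth.

    Per neuron: fluorescence(t) = F_base * (1 + dff_signal(t)) + Gaussian
    noise with SD ``noise_sd * F_base``.  Responders per stimulus are
    Bernoulli draws; each responder carries one transient whose onset lies
    within the first ``onset_jitter_frames`` frames of the application
    window.  Identical ``(config, protocol)`` pairs reproduce bit-identical
    output; per-neuron RNG substreams are spawned deterministically from the
    seed, so neuron ``i`` is unchanged by the presence of later neurons.
    """
    protocol = protocol or ImagingProtocol()
    n_frames = protocol.n_frames
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(config.n_neurons + 1)]
    rng_global = streams[-1]

    field_um = protocol.field_size_um
    centroids = rng_global.uniform(0, field_um, size=(config.n_neurons, 2))

    def p_resp(stim: str) -> float:
        if isinstance(config.responder_probability, dict):
            return config.responder_probability[stim]
        return config.responder_probability

    traces = np.empty((config.n_neurons, n_frames))
    truths: list[NeuronGroundTruth] = []
    for i in range(config.n_neurons):
        rng = streams[i]
        f_base = float(np.exp(rng.normal(config.baseline_mu, config.baseline_sigma)))
        area = float(np.exp(rng.normal(config.area_mu, config.area_sigma)))
        dff_signal = np.zeros(n_frames)
        flags: dict[str, bool] = {}
        amps: dict[str, float] = {}
        onsets: dict[str, int] = {}
        for stim in protocol.stimulus_labels:
            responds = bool(rng.random() < p_resp(stim))
            win = protocol.application_frames(stim)
            jitter = min(config.onset_jitter_frames, len(win))
            onset = int(win.start + rng.integers(0, jitter))
            amp = 0.0
            if responds:
                amp = float(
                    max(
                        np.exp(rng.normal(config.amplitude_mu, config.amplitude_sigma)),
                        config.amplitude_min,
                    )
                )
                dff_signal += amp * _kernel_samples(
                    config, protocol, onset, win.stop, n_frames,
                    epoch_end=protocol.epoch_frames(stim).stop,
                )
            flags[stim] = responds
            amps[stim] = amp
            onsets[stim] = onset
        noise = rng.normal(0.0, config.noise_sd * f_base, size=n_frames)
        traces[i] = np.maximum(f_base * (1.0 + dff_signal) + noise, 0.0)
        truths.append(
            NeuronGroundTruth(
                neuron_id=i,
                centroid_um=(float(centroids[i, 0]), float(centroids[i, 1])),
                area_um2=area,
                baseline_fluorescence=f_base,
                responder_flags=flags,
                transient_amplitude=amps,
                transient_onset_frame=onsets,
                rise_tau_s=config.rise_tau_s,
                decay_tau_s=config.decay_tau_s,
            )
        )

    session = ImagingSession(
        protocol=protocol,
        traces=traces,
        neuron_ids=np.arange(config.n_neurons),
        areas_um2=np.array([t.area_um2 for t in truths]),
    )
    return session, truths


def render_stack(
    session: ImagingSession,
    truths: list[NeuronGroundTruth],
    forbid_overlap: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a session as a movie plus an ROI label image.

    Each neuron is a 2-D Gaussian blob (SD = soma radius / 2) whose ROI is
    the disc of its soma radius around the centroid.  The blob is scaled so
    that its mean over the ROI equals the neuron's trace value, hence
    mean-ROI extraction of a noiseless, non-overlapping stack reproduces the
    generating traces.  ROI labels are ``neuron_id + 1``.  With
    ``forbid_overlap`` a neuron whose disc would touch an already-claimed
    pixel is re-placed on a coarse grid; overlapping pixels otherwise keep
    the first neuron's label and sum the fluorescence.
    """
    proto = session.protocol
    h, w = proto.grid_shape
    px = proto.pixel_size_um
    n_frames = proto.n_frames
    stack = np.zeros((n_frames, h, w), dtype=np.float32)
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]

    order = np.argsort([-t.area_um2 for t in truths])  # big somata first
    for i in order:
        t = truths[i]
        r_um = np.sqrt(t.area_um2 / np.pi)
        cx, cy = t.centroid_um[0] / px, t.centroid_um[1] / px
        r_px = max(r_um / px, 1.0)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = d2 <= r_px**2
        if forbid_overlap and np.any(labels[mask] > 0):
            placed = False
            step = int(np.ceil(2 * r_px)) + 2
            for gy in range(step, h - step, step):
                for gx in range(step, w - step, step):
                    d2 = (xx - gx) ** 2 + (yy - gy) ** 2
                    mask = d2 <= r_px**2
                    if not np.any(labels[mask] > 0):
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise RuntimeError("could not place neuron without overlap")
        if not mask.any():
            continue
        blob = np.exp(-d2 / (2 * (r_px / 2) ** 2))
        blob /= blob[mask].mean()  # ROI mean of the profile is 1
        labels[mask & (labels == 0)] = t.neuron_id + 1
        trace = session.traces[session.neuron_ids == t.neuron_id][0]
        stack += (trace[:, None, None] * blob[None, :, :] * mask[None, :, :]).astype(
            np.float32
        )
    return stack, labels
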