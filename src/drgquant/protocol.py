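"""Acquisition protocol for stimulus-locked DRG calcium imaging.

A recording consists of a global force-free baseline block followed by one
epoch per stimulus.  Each epoch has a pre-stimulus block, the stimulus
application block, and a post-stimulus block.  Defaults follow a two-photon
knee-stimulation protocol: 0.7 Hz frame rate, 30 baseline frames, 10/10/10
epoch frames, a 981.36 x 981.36 um field scanned at 1.92 um/pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class ImagingProtocol:
    """Frame layout and geometry of a stimulus-locked imaging session.

    Parameters
    ----------
    frame_rate
        Acquisition rate in frames per second.
    n_global_baseline
        Number of force-free baseline frames at the start of the recording.
    epoch_layout
        ``(n_pre, n_stim, n_post)`` frame counts for every stimulus epoch.
    stimulus_labels
        Ordered stimulus names, one epoch each (e.g. ``("30g", "100g")``).
    field_size_um
        Scanned field edge length in micrometres (square field).
    pixel_size_um
        Pixel edge length in micrometres.
    """

    frame_rate: float = 0.7
    n_global_baseline: int = 30
    epoch_layout: tuple[int, int, int] = (10, 10, 10)
    stimulus_labels: tuple[str, ...] = ("30g", "100g")
    field_size_um: float = 981.36
    pixel_size_um: float = 1.92

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_global_baseline < 1:
            raise ValueError("n_global_baseline must be >= 1")
        if len(self.epoch_layout) != 3 or any(n < 1 for n in self.epoch_layout):
            raise ValueError("epoch_layout must be three frame counts >= 1")
        if not self.stimulus_labels:
            raise ValueError("at least one stimulus label is required")
        if len(set(self.stimulus_labels)) != len(self.stimulus_labels):
            raise ValueError("stimulus labels must be unique")
        n_px = self.field_size_um / self.pixel_size_um
        if abs(n_px - round(n_px)) > 0.2:
            raise ValueError(
                "field_size_um must divide into an integer pixel grid "
                f"(got {n_px:.3f} pixels per edge)"
            )

    # -- frame bookkeeping -------------------------------------------------

    @property
    def epoch_length(self) -> int:
        return sum(self.epoch_layout)

    @property
    def n_frames(self) -> int:
        """Total frame count of the recording."""
        return self.n_global_baseline + len(self.stimulus_labels) * self.epoch_length

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = round(self.field_size_um / self.pixel_size_um)
        return (n, n)

    @property
    def global_baseline_frames(self) -> range:
        """Frame indices of the force-free baseline block."""
        return range(self.n_global_baseline)

    def _epoch_start(self, stimulus: str) -> int:
        try:
            i = self.stimulus_labels.index(stimulus)
        except ValueError:
            raise KeyError(f"unknown stimulus {stimulus!r}") from None
        return self.n_global_baseline + i * self.epoch_length

    def epoch_frames(self, stimulus: str) -> range:
        """All frames (pre + stim + post) of one stimulus epoch."""
        s = self._epoch_start(stimulus)
        return range(s, s + self.epoch_length)

    def prestim_frames(self, stimulus: str) -> range:
        s = self._epoch_start(stimulus)
        return range(s, s + self.epoch_layout[0])

    def application_frames(self, stimulus: str) -> range:
        """Frames during which the stimulus is applied."""
        s = self._epoch_start(stimulus) + self.epoch_layout[0]
        return range(s, s + self.epoch_layout[1])

    def poststim_frames(self, stimulus: str) -> range:
        s = self._epoch_start(stimulus) + self.epoch_layout[0] + self.epoch_layout[1]
        return range(s, s + self.epoch_layout[2])

    # -- (de)serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ImagingProtocol":
        d = json.loads(Path(path).read_text())
        d["epoch_layout"] = tuple(d["epoch_layout"])
        d["stimulus_labels"] = tuple(d["stimulus_labels"])
        return cls(**d)
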