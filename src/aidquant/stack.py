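"""Canonical in-memory container for multi-channel time-lapse stacks.

Axis order is fixed to (T, Z, C, Y, X) throughout the package; readers are
responsible for permuting whatever order a file delivers into this one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeLapseStack"]


@dataclass
class TimeLapseStack:
    """Multi-channel, multi-plane, time-stamped pixel data.

    Parameters
    ----------
    pixels
        Array indexed ``(t, z, channel, row, col)``, arbitrary units >= 0.
    timestamps_h
        Acquisition time of each frame in hours, strictly increasing.
    channel_names
        One label per channel, e.g. ``["target", "reporter"]``.
    pixel_size_um
        Lateral pixel size in micrometres.
    z_step_um
        Axial plane spacing in micrometres.
    inducer_time_h
        Clock time (hours) at which the degradation inducer was added.
        Metadata, never inferred from the data.
    """

    pixels: np.ndarray
    timestamps_h: np.ndarray
    channel_names: list[str] = field(default_factory=lambda: ["ch0"])
    pixel_size_um: float = 0.1
    z_step_um: float = 0.8
    inducer_time_h: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must be 5-D (T,Z,C,Y,X), got {self.pixels.ndim}-D"
            )
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        if self.timestamps_h.shape != (self.pixels.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.timestamps_h.size > 1 and not np.all(
            np.diff(self.timestamps_h) > 0
        ):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.channel_names) != self.pixels.shape[2]:
            raise ValueError("one name per channel required")

    @property
    def n_timepoints(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def pre_inducer_timepoints(self) -> np.ndarray:
        """Indices of frames acquired strictly before inducer addition."""
        if self.inducer_time_h is None:
            raise ValueError("stack has no inducer time set")
        return np.flatnonzero(self.timestamps_h < self.inducer_time_h)
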