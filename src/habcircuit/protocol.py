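"""Light-stimulus protocol: ordered on/off pulse schedule.

The default experiment delivers 4 pulses of blue light, each 20 s long and
followed by 20 s of darkness, while fluorescence is sampled at 1 Hz.  The
protocol object owns the mapping from wall-clock time to light/dark windows
so every downstream stage (kernel simulation, cycle averaging, subtype
labelling) agrees on the stimulus alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LightProtocol", "make_protocol", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class LightProtocol:
    """An ordered, non-overlapping schedule of light pulses.

    Parameters
    ----------
    pulse_onsets : tuple of float
        Start time of each light pulse, seconds, strictly increasing.
    pulse_duration : float
        Length of each light pulse, seconds.
    inter_pulse_dark : float
        Dark period following each pulse, seconds.
    total_duration : float
        Total span of the recording, seconds.
    sample_rate : float
        Sampling rate of the fluorescence traces, Hz.
    """

    pulse_onsets: tuple = field(default_factory=tuple)
    pulse_duration: float = 20.0
    inter_pulse_dark: float = 20.0
    total_duration: float = 160.0
    sample_rate: float = 1.0

    def __post_init__(self):
        onsets = tuple(float(t) for t in self.pulse_onsets)
        object.__setattr__(self, "pulse_onsets", onsets)
        if self.pulse_duration <= 0 or self.inter_pulse_dark <= 0:
            raise ValueError("pulse durations must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(onsets) == 0:
            raise ValueError("protocol needs at least one pulse")
        diffs = np.diff(onsets)
        if np.any(diffs < self.pulse_duration):
            raise ValueError("pulses overlap or are not strictly increasing")
        if onsets[0] < 0 or onsets[-1] + self.pulse_duration > self.total_duration + 1e-9:
            raise ValueError("pulse windows must lie within [0, total_duration]")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets)

    @property
    def cycle_duration(self) -> float:
        """One light+dark cycle, seconds."""
        return self.pulse_duration + self.inter_pulse_dark

    @property
    def n_samples(self) -> int:
        """Samples on the closed grid [0, total_duration] at sample_rate."""
        return int(round(self.total_duration * self.sample_rate)) + 1

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_duration * self.sample_rate))

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def light_windows(self) -> list:
        """[(on, off), ...] in seconds."""
        return [(t, t + self.pulse_duration) for t in self.pulse_onsets]

    @property
    def dark_windows(self) -> list:
        """Dark windows following each pulse, clipped to the recording."""
        out = []
        for t in self.pulse_onsets:
            a = t + self.pulse_duration
            b = min(a + self.inter_pulse_dark, self.total_duration)
            if b > a:
                out.append((a, b))
        return out

    @property
    def offsets(self) -> np.ndarray:
        """Light→dark transition times, seconds."""
        return np.array([t + self.pulse_duration for t in self.pulse_onsets])

    def light_mask(self, times: np.ndarray | None = None) -> np.ndarray:
        """Boolean mask: True where the light is on (half-open windows)."""
        t = self.time_axis if times is None else np.asarray(times, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for a, b in self.light_windows:
            mask |= (t >= a - 1e-12) & (t < b - 1e-12)
        return mask

    def to_dict(self) -> dict:
        return {
            "pulse_onsets": list(self.pulse_onsets),
            "pulse_duration": self.pulse_duration,
            "inter_pulse_dark": self.inter_pulse_dark,
            "total_duration": self.total_duration,
            "sample_rate": self.sample_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightProtocol":
        return cls(
            pulse_onsets=tuple(d["pulse_onsets"]),
            pulse_duration=d["pulse_duration"],
            inter_pulse_dark=d["inter_pulse_dark"],
            total_duration=d["total_duration"],
            sample_rate=d["sample_rate"],
        )


def make_protocol(n_pulses: int = 4, on_dur: float = 20.0, off_dur: float = 20.0,
                  rate: float = 1.0, lead_in: float = 0.0) -> LightProtocol:
    """Build a regular pulse train: ``n_pulses`` cycles of light then dark.

    Light starts at t=``lead_in`` (0 by default, i.e. no dark lead-in) and each
    pulse of ``on_dur`` seconds is followed by ``off_dur`` seconds of dark.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if on_dur <= 0 or off_dur <= 0:
        raise ValueError("on/off durations must be positive")
    if lead_in < 0:
        raise ValueError("lead_in must be >= 0")
    cycle = on_dur + off_dur
    onsets = tuple(lead_in + i * cycle for i in range(n_pulses))
    return LightProtocol(
        pulse_onsets=onsets,
        pulse_duration=on_dur,
        inter_pulse_dark=off_dur,
        total_duration=lead_in + n_pulses * cycle,
        sample_rate=rate,
    )


#: The experiment's stimulus: 4 × (20 s blue light + 20 s dark) at 1 Hz.
DEFAULT_PROTOCOL = make_protocol(4, 20.0, 20.0, 1.0)
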