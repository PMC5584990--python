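"""Core time-series containers shared across the toolkit.

All traces are uniformly sampled and carry explicit units in their field
names (``_deg``, ``_mV``, ``_s``).  Angles are degrees throughout; the
horizontal (nasal-temporal) axis is the only one modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyeTrace",
    "SensorTrace",
    "StimulusTrace",
    "VelocityTrace",
    "ExclusionMask",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class EyeTrace:
    """Horizontal angular eye position, uniformly sampled.

    Positive direction follows the configured nasal/temporal convention
    (rightward-positive by default in binocular work).
    """

    time_s: np.ndarray
    position_deg: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.position_deg = _as_1d(self.position_deg, "position_deg")
        if self.time_s.shape != self.position_deg.shape:
            raise ValueError("time_s and position_deg must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        # NaN marks gaps (e.g. invalid video frames); infinities are rejected
        if self.position_deg.size and np.isinf(self.position_deg).any():
            raise ValueError("position_deg must not contain infinities")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class SensorTrace:
    """Two-channel AMR sensor voltages with optional TTL sync-pulse times."""

    time_s: np.ndarray
    v_mV: np.ndarray  # shape (n, 2)
    sample_rate_hz: float
    ttl_pulse_times_s: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        if self.v_mV.ndim != 2 or self.v_mV.shape[1] != 2:
            raise ValueError("v_mV must have shape (n, 2): exactly two channels")
        if self.v_mV.shape[0] != self.time_s.size:
            raise ValueError("v_mV and time_s lengths differ")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.ttl_pulse_times_s is not None:
            self.ttl_pulse_times_s = _as_1d(self.ttl_pulse_times_s, "ttl_pulse_times_s")
            if self.time_s.size and self.ttl_pulse_times_s.size:
                lo, hi = self.time_s[0], self.time_s[-1]
                if (self.ttl_pulse_times_s < lo).any() or (self.ttl_pulse_times_s > hi).any():
                    raise ValueError("TTL pulse times fall outside the trace time range")

    def __len__(self) -> int:
        return self.time_s.size

    def channel(self, index: int) -> np.ndarray:
        """Return one voltage channel (0-based index)."""
        return self.v_mV[:, index]


@dataclass
class StimulusTrace:
    """Sinusoidal vestibular/visual stimulus: position and velocity profiles."""

    time_s: np.ndarray
    position_deg: np.ndarray
    velocity_deg_s: np.ndarray
    frequency_hz: float
    peak_velocity_deg_s: float

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.position_deg = _as_1d(self.position_deg, "position_deg")
        self.velocity_deg_s = _as_1d(self.velocity_deg_s, "velocity_deg_s")
        n = self.time_s.size
        if self.position_deg.size != n or self.velocity_deg_s.size != n:
            raise ValueError("stimulus arrays must share one length")

    @property
    def sample_rate_hz(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("need at least two samples to infer a rate")
        return 1.0 / (self.time_s[1] - self.time_s[0])


@dataclass
class VelocityTrace:
    """Differentiated trace with a mandatory units tag.

    ``units`` is ``"deg/s"`` for video-derived eye velocity and ``"mV/s"``
    for differentiated sensor voltage.  ``window_ms`` records the sliding
    window used for the slope estimate.
    """

    time_s: np.ndarray
    value: np.ndarray
    units: str
    window_ms: float

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape[0] != self.time_s.size:
            raise ValueError("value and time_s lengths differ")
        if not self.units:
            raise ValueError("units tag is mandatory")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class ExclusionMask:
    """Per-sample boolean exclusion mask (True = excluded)."""

    excluded: np.ndarray
    source: str = "video"  # video | sensor | union
    pad_ms: float = 0.0

    def __post_init__(self):
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.ndim != 1:
            raise ValueError("mask must be 1-D")

    def __len__(self) -> int:
        return self.excluded.size

    def union(self, other: "ExclusionMask") -> "ExclusionMask":
        """Elementwise OR: a sample excluded in either source is excluded."""
        if len(self) != len(other):
            raise ValueError("masks must have equal length to union")
        return ExclusionMask(
            excluded=self.excluded | other.excluded,
            source="union",
            pad_ms=max(self.pad_ms, other.pad_ms),
        )

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded

    def intervals_s(self, time_s: np.ndarray) -> list[tuple[float, float]]:
        """Excluded intervals as (start_s, end_s) pairs."""
        m = self.excluded
        if m.size != np.asarray(time_s).size:
            raise ValueError("time axis length mismatch")
        edges = np.flatnonzero(np.diff(m.astype(int)))
        starts = list(edges[m[edges + 1]] + 1)
        ends = list(edges[~m[edges + 1]] + 1)
        if m.size and m[0]:
            starts.insert(0, 0)
        if m.size and m[-1]:
            ends.append(m.size)
        return [(float(time_s[s]), float(time_s[e - 1])) for s, e in zip(starts, ends)]
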