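"""EMG preprocessing: MVC-based amplitude normalization and pedal-cycle segmentation.

Surface-EMG amplitude depends on electrode placement and skin impedance, which change
between sessions.  Recordings are therefore expressed relative to the RMS amplitude of
maximum voluntary contractions (MVC) recorded in the same session.  Pedal cycles are
delimited by a crank-mounted magnetic switch that produces one pulse per revolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EmgRecording",
    "CycleEvents",
    "rms",
    "mvc_rms_reference",
    "normalize",
    "detect_cycles",
    "select_cycle_block",
    "work_rate",
    "cadence_from_events",
]


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty signal")
    return float(np.sqrt(np.mean(np.square(x))))


@dataclass
class EmgRecording:
    """A uniformly sampled single-channel EMG signal.

    Parameters
    ----------
    samples
        Signed amplitude samples.
    sampling_rate
        Sampling rate in Hz.
    units
        Amplitude units label, e.g. ``"mV"`` or ``"MVC"`` after normalization.
    meta
        Free-form session metadata (subject, condition, interval boundaries, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    units: str = "mV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def rms(self) -> float:
        return rms(self.samples)


@dataclass
class CycleEvents:
    """Ordered pedal-cycle onset times (seconds).

    ``n`` onsets delimit ``n - 1`` cycles; cycle ``i`` is the half-open interval
    ``[onsets[i], onsets[i + 1])``.
    """

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size < 2:
            raise ValueError("at least 2 onsets are required to define a cycle")
        if not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.onsets.size - 1

    def intervals(self) -> list[tuple[float, float]]:
        """Half-open cycle intervals ``[t_start, t_end)``."""
        return list(zip(self.onsets[:-1], self.onsets[1:]))

    def durations(self) -> np.ndarray:
        return np.diff(self.onsets)


def mvc_rms_reference(mvc_recordings: list[EmgRecording]) -> float:
    """Arithmetic mean of the per-trial RMS amplitudes of the MVC recordings.

    This is the session's amplitude calibration constant: dividing a recording by it
    expresses amplitude as a fraction of mean MVC RMS.

    Raises
    ------
    ValueError
        If no recordings are given or the reference would be zero (all-zero MVCs),
        which would make the downstream normalization divide by zero.
    """
    if len(mvc_recordings) == 0:
        raise ValueError("at least one MVC recording is required")
    reference = float(np.mean([r.rms() for r in mvc_recordings]))
    if reference <= 0.0:
        raise ValueError("invalid MVC calibration: all recordings have zero RMS")
    return reference


def normalize(recording: EmgRecording, reference: float) -> EmgRecording:
    """Divide a recording by the MVC RMS reference, yielding dimensionless units."""
    if not reference > 0:
        raise ValueError("normalization reference must be positive")
    return replace(
        recording,
        samples=recording.samples / reference,
        units="MVC",
        meta=dict(recording.meta),
    )


def detect_cycles(
    switch: np.ndarray,
    sampling_rate: float,
    debounce_s: float = 0.05,
) -> CycleEvents:
    """Detect pedal-cycle onsets from the crank-switch channel.

    Onsets are rising crossings of the channel's half-range threshold
    ``(min + max) / 2``, which makes detection invariant to amplitude scaling.
    Crossings closer than ``debounce_s`` to the previously accepted onset are treated
    as contact bounce and ignored (default 50 ms, far below the 0.75 s cycle period
    at 80 rpm).
    """
    switch = np.asarray(switch, dtype=float)
    if switch.ndim != 1 or switch.size < 2:
        raise ValueError("switch channel must be a 1-D signal with >= 2 samples")
    if not sampling_rate > 0:
        raise ValueError("sampling_rate must be positive")
    lo, hi = switch.min(), switch.max()
    if hi <= lo:
        raise ValueError("switch channel is constant: no rising edges")
    thr = 0.5 * (lo + hi)
    above = switch >= thr
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:  # channel starts high: the first sample is an onset
        edges = np.concatenate(([0], edges))
    # debounce: drop edges within debounce_s of the last accepted one
    kept: list[int] = []
    min_gap = debounce_s * sampling_rate
    for e in edges:
        if not kept or e - kept[-1] >= min_gap:
            kept.append(int(e))
    if len(kept) < 2:
        raise ValueError("fewer than 2 rising edges: no cycles detected")
    return CycleEvents(np.asarray(kept, dtype=float) / sampling_rate)


def select_cycle_block(events: CycleEvents, which: str, n: int = 10) -> CycleEvents:
    """Select ``n`` contiguous cycles from the ``"first"`` or ``"last"`` end.

    Returns a :class:`CycleEvents` with ``n + 1`` onsets (``n`` cycles), order
    preserved.
    """
    if n < 1:
        raise ValueError("block size must be >= 1")
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    if events.n_cycles < n:
        raise ValueError(
            f"requested {n} cycles but only {events.n_cycles} are available"
        )
    onsets = events.onsets[: n + 1] if which == "first" else events.onsets[-(n + 1):]
    return CycleEvents(onsets)


def work_rate(cadence_rpm, load) -> np.ndarray:
    """External work rate as cadence x load (the ergometer's flywheel loading).

    Both arguments may be scalars or equal-length series; the product is elementwise.
    """
    cadence_rpm = np.atleast_1d(np.asarray(cadence_rpm, dtype=float))
    load = np.atleast_1d(np.asarray(load, dtype=float))
    if cadence_rpm.size != load.size and 1 not in (cadence_rpm.size, load.size):
        raise ValueError("cadence and load series must have matching lengths")
    if np.any(cadence_rpm < 0) or np.any(load < 0):
        raise ValueError("cadence and load must be non-negative")
    return cadence_rpm * load


def cadence_from_events(events: CycleEvents) -> np.ndarray:
    """Per-cycle cadence in rpm from consecutive onset spacing (60 / period)."""
    return 60.0 / events.durations()
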