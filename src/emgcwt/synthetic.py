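"""Synthetic surface-EMG generator with known spectral and amplitude ground truth.

Emulates single-leg cycling EMG as captured in an interval-exercise session: one
activation burst per pedal cycle at a fixed cadence, burst spectral content
concentrated in the tens-to-hundreds of Hz, a low-level baseline between bursts, a
crank-switch pulse at every cycle onset, and separate MVC calibration recordings.
Within-interval fatigue appears as a linear cycle-by-cycle drift of the burst median
frequency (downward) and burst RMS (upward).

Each burst is band-limited noise built by inverse FFT of a deterministic Gaussian
amplitude spectrum centred on the cycle's target median frequency with uniformly
random phases.  Because the amplitude spectrum is symmetric about the target, the
burst's theoretical median frequency equals the target exactly, and because the burst
is rescaled to its target RMS after windowing, the amplitude ground truth is exact as
well.  A raised-cosine (Tukey) envelope avoids the spectral splatter a rectangular
gate would add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .preprocessing import EmgRecording

__all__ = ["SimulationConfig", "GroundTruth", "generate_session", "generate_mvc"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated session.

    Amplitudes are in mV-equivalent units; ``burst_rms_*`` and ``median_freq_*``
    interpolate linearly from the first to the last cycle.  ``spectral_bandwidth_hz``
    is twice the standard deviation of the Gaussian burst amplitude response.
    """

    sampling_rate: float = 2048.0
    cadence_rpm: float = 80.0
    n_cycles: int = 80
    burst_duty: float = 0.4
    median_freq_start_hz: float = 80.0
    median_freq_end_hz: float = 80.0
    spectral_bandwidth_hz: float = 40.0
    burst_rms_start: float = 0.5
    burst_rms_end: float = 0.5
    baseline_noise_rms: float = 0.02
    mvc_rms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.cadence_rpm > 0:
            raise ValueError("cadence must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 < self.burst_duty <= 1:
            raise ValueError("burst_duty must be in (0, 1]")
        for f in (self.median_freq_start_hz, self.median_freq_end_hz):
            if not 0 < f < nyq:
                raise ValueError("target median frequencies must be in (0, Nyquist)")
        if not self.spectral_bandwidth_hz > 0:
            raise ValueError("spectral bandwidth must be positive")
        for a in (self.burst_rms_start, self.burst_rms_end,
                  self.baseline_noise_rms, self.mvc_rms):
            if a < 0:
                raise ValueError("RMS amplitudes must be non-negative")

    @property
    def cycle_period_s(self) -> float:
        return 60.0 / self.cadence_rpm

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_period_s * self.sampling_rate))


@dataclass
class GroundTruth:
    """Per-cycle true burst parameters and the cycle onset times."""

    median_freq_hz: np.ndarray
    burst_rms: np.ndarray
    cycle_onsets_s: np.ndarray

    def __post_init__(self) -> None:
        n = self.median_freq_hz.size
        if not (self.burst_rms.size == n and self.cycle_onsets_s.size == n):
            raise ValueError("ground-truth vectors must all have length n_cycles")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(self.median_freq_hz.size),
                "onset_s": self.cycle_onsets_s,
                "median_freq_hz": self.median_freq_hz,
                "burst_rms": self.burst_rms,
            }
        )


def _linear_trajectory(start: float, end: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([start])
    return start + (end - start) * np.arange(n) / (n - 1)


def _shaped_noise(
    n: int,
    median_freq_hz: float,
    bandwidth_hz: float,
    sampling_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited noise of length ``n``: Gaussian amplitude spectrum centred on
    ``median_freq_hz`` (std ``bandwidth_hz / 2``), uniformly random phases, zero DC."""
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    sigma = bandwidth_hz / 2.0
    amp = np.exp(-((freqs - median_freq_hz) ** 2) / (2.0 * sigma**2))
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0  # zero-mean
    if n % 2 == 0:
        spectrum[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    return np.fft.irfft(spectrum, n)


def _windowed_shaped_burst(
    n: int,
    median_freq_hz: float,
    bandwidth_hz: float,
    sampling_rate: float,
    window: np.ndarray,
    rng: np.random.Generator,
    n_refine: int = 8,
) -> np.ndarray:
    """A Tukey-enveloped burst whose spectrum matches the target shape.

    Multiplying a random-phase realization by the envelope perturbs its amplitude
    spectrum (adjacent bins mix with random phases), which jitters the realized
    median frequency by a couple of Hz.  A few alternating projections — re-impose
    the target amplitude spectrum, re-apply the envelope — shrink that jitter to
    well under 1 Hz while keeping the taper.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    sigma = bandwidth_hz / 2.0
    amp = np.exp(-((freqs - median_freq_hz) ** 2) / (2.0 * sigma**2))
    x = _shaped_noise(n, median_freq_hz, bandwidth_hz, sampling_rate, rng)
    for _ in range(n_refine):
        spectrum = amp * np.exp(1j * np.angle(np.fft.rfft(x * window)))
        spectrum[0] = 0.0
        x = np.fft.irfft(spectrum, n)
    return x * window


def generate_session(
    config: SimulationConfig,
) -> tuple[EmgRecording, np.ndarray, GroundTruth]:
    """Simulate one exercise interval: EMG, switch channel, and ground truth.

    The signal spans ``n_cycles`` full cycles.  Each cycle starts with a switch pulse
    and contains one Tukey-windowed burst of duration ``burst_duty`` x cycle period,
    rescaled to that cycle's exact target RMS (RMS measured over the burst support).
    Between bursts the signal is white baseline noise.
    """
    spc = config.samples_per_cycle
    n_total = spc * config.n_cycles
    n_burst = max(1, int(round(config.burst_duty * spc)))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))

    f_traj = _linear_trajectory(
        config.median_freq_start_hz, config.median_freq_end_hz, config.n_cycles
    )
    rms_traj = _linear_trajectory(
        config.burst_rms_start, config.burst_rms_end, config.n_cycles
    )

    if config.baseline_noise_rms > 0:
        emg = rng.normal(0.0, config.baseline_noise_rms, n_total)
    else:
        emg = np.zeros(n_total)

    window = windows.tukey(n_burst, alpha=0.25) if n_burst > 1 else np.ones(1)
    for i in range(config.n_cycles):
        burst = _windowed_shaped_burst(
            n_burst, f_traj[i], config.spectral_bandwidth_hz, config.sampling_rate,
            window, rng,
        )
        cur = np.sqrt(np.mean(burst**2))
        burst = burst * (rms_traj[i] / cur) if cur > 0 and rms_traj[i] > 0 else 0.0 * burst
        start = i * spc
        emg[start : start + n_burst] += burst

    switch = np.zeros(n_total)
    pulse = max(1, int(round(0.01 * config.sampling_rate)))
    onsets = np.arange(config.n_cycles) * spc
    for o in onsets:
        switch[o : o + pulse] = 1.0

    recording = EmgRecording(
        samples=emg,
        sampling_rate=config.sampling_rate,
        units="mV",
        meta={"synthetic": True, "seed": config.seed},
    )
    truth = GroundTruth(
        median_freq_hz=f_traj,
        burst_rms=rms_traj,
        cycle_onsets_s=onsets / config.sampling_rate,
    )
    return recording, switch, truth


def generate_mvc(
    config: SimulationConfig, n_reps: int = 3, duration_s: float = 4.0
) -> list[EmgRecording]:
    """Simulate MVC calibration recordings.

    Each recording is band-limited noise with the session's spectral shape, rescaled
    to RMS exactly ``config.mvc_rms``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * config.sampling_rate))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    out = []
    for _ in range(n_reps):
        x = _shaped_noise(
            n,
            config.median_freq_start_hz,
            config.spectral_bandwidth_hz,
            config.sampling_rate,
            rng,
        )
        cur = np.sqrt(np.mean(x**2))
        x = x * (config.mvc_rms / cur) if cur > 0 and config.mvc_rms > 0 else 0.0 * x
        out.append(
            EmgRecording(
                samples=x,
                sampling_rate=config.sampling_rate,
                units="mV",
                meta={"synthetic": True, "mvc": True, "seed": config.seed},
            )
        )
    return out
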