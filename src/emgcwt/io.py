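"""Flat-file persistence for sessions and intermediate arrays.

Sessions are stored as delimited text (one ``(time, value)`` pair per line) so they
can be inspected and produced by any acquisition toolchain; array intermediates
(scalograms, cycle maps) are stored as a ``.npy`` container next to a JSON header
carrying axes and parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cwt import FrequencyGrid, MorletParams, Scalogram
from .cyclemap import CycleMap
from .preprocessing import EmgRecording
from .synthetic import GroundTruth, SimulationConfig

__all__ = [
    "write_session",
    "read_session",
    "write_simulation_config",
    "read_simulation_config",
    "save_scalogram",
    "load_scalogram",
    "save_cycle_map",
    "load_cycle_map",
]

_FLOAT_FMT = "%.10g"


def write_session(
    directory,
    stem: str,
    recording: EmgRecording,
    switch: np.ndarray,
    truth: GroundTruth | None = None,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write a session as delimited text plus optional truth/config sidecars.

    Produces ``<stem>_emg.txt`` and ``<stem>_switch.txt`` (two columns: time in
    seconds, value), ``<stem>_truth.csv``, and ``<stem>_config.txt``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = recording.times
    paths = {}
    emg_path = directory / f"{stem}_emg.txt"
    np.savetxt(emg_path, np.column_stack([t, recording.samples]), fmt=_FLOAT_FMT, delimiter="\t")
    paths["emg"] = emg_path
    sw_path = directory / f"{stem}_switch.txt"
    np.savetxt(sw_path, np.column_stack([t, switch]), fmt=_FLOAT_FMT, delimiter="\t")
    paths["switch"] = sw_path
    if truth is not None:
        truth_path = directory / f"{stem}_truth.csv"
        truth.to_frame().to_csv(truth_path, index=False, float_format=_FLOAT_FMT)
        paths["truth"] = truth_path
    if config is not None:
        cfg_path = directory / f"{stem}_config.txt"
        write_simulation_config(cfg_path, config)
        paths["config"] = cfg_path
    return paths


def read_session(
    emg_path, switch_path, sampling_rate: float | None = None
) -> tuple[EmgRecording, np.ndarray]:
    """Read an EMG + switch session from delimited text files.

    The sampling rate is inferred from the time column unless given explicitly.
    """
    emg = np.loadtxt(emg_path)
    sw = np.loadtxt(switch_path)
    if emg.ndim != 2 or emg.shape[1] < 2:
        raise ValueError("EMG file must have (time, value) columns")
    if sampling_rate is None:
        dt = np.median(np.diff(emg[:, 0]))
        sampling_rate = 1.0 / dt
    recording = EmgRecording(samples=emg[:, 1], sampling_rate=float(sampling_rate))
    switch = sw[:, 1] if sw.ndim == 2 else sw
    if switch.size != recording.samples.size:
        raise ValueError("EMG and switch files have different lengths")
    return recording, switch


def write_simulation_config(path, config: SimulationConfig) -> None:
    """Serialize a simulation config as flat ``key = value`` text."""
    lines = [f"{k} = {v}" for k, v in vars(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_simulation_config(path) -> SimulationConfig:
    fields = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        fields[k.strip()] = v.strip()
    kwargs = {}
    for k, v in fields.items():
        kwargs[k] = int(v) if k in ("n_cycles", "seed") else float(v)
    return SimulationConfig(**kwargs)


def _save_array(path: Path, arr: np.ndarray, header: dict) -> None:
    np.save(path.with_suffix(".npy"), arr)
    path.with_suffix(".json").write_text(json.dumps(header, indent=2) + "\n")


def save_scalogram(path, scalogram: Scalogram) -> None:
    path = Path(path)
    header = {
        "kind": "scalogram",
        "frequencies_hz": scalogram.grid.frequencies.tolist(),
        "sampling_rate_hz": scalogram.sampling_rate,
        "t_start_s": float(scalogram.times[0]),
        "coi_halfwidth_s": scalogram.coi_halfwidth_s.tolist(),
        "morlet_bandwidth": scalogram.params.bandwidth,
        "morlet_center_frequency": scalogram.params.center_frequency,
        "normalization": scalogram.normalization,
    }
    _save_array(path, scalogram.power, header)


def load_scalogram(path) -> Scalogram:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    if header.get("kind") != "scalogram":
        raise ValueError(f"{path}: not a scalogram container")
    power = np.load(path.with_suffix(".npy"))
    grid = FrequencyGrid(np.asarray(header["frequencies_hz"]), header["sampling_rate_hz"])
    times = header["t_start_s"] + np.arange(power.shape[1]) / header["sampling_rate_hz"]
    return Scalogram(
        power=power,
        grid=grid,
        times=times,
        coi_halfwidth_s=np.asarray(header["coi_halfwidth_s"]),
        params=MorletParams(header["morlet_bandwidth"], header["morlet_center_frequency"]),
        normalization=header["normalization"],
    )


def save_cycle_map(path, cycle_map: CycleMap) -> None:
    path = Path(path)
    header = {
        "kind": "cycle_map",
        "frequencies_hz": cycle_map.frequencies.tolist(),
        "percent": cycle_map.percent.tolist(),
        "n_cycles_averaged": cycle_map.n_cycles_averaged,
        "condition": cycle_map.condition,
        "block": cycle_map.block,
        "normalized_to": cycle_map.normalized_to,
    }
    _save_array(path, cycle_map.power, header)


def load_cycle_map(path) -> CycleMap:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    if header.get("kind") != "cycle_map":
        raise ValueError(f"{path}: not a cycle-map container")
    power = np.load(path.with_suffix(".npy"))
    return CycleMap(
        power=power,
        frequencies=np.asarray(header["frequencies_hz"]),
        percent=np.asarray(header["percent"]),
        n_cycles_averaged=header["n_cycles_averaged"],
        condition=header["condition"],
        block=header["block"],
        normalized_to=header["normalized_to"],
    )
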