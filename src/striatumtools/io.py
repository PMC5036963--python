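"""Readers and writers for the pipeline's plain-text data formats.

Spike trains are newline-delimited seconds with a metadata table; field
signals are delimited samples with a YAML sidecar stating the sampling
rate; contours and neuron censuses are TSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phase import SampledSignal
from .spikes import SpikeTrain
from .topography import PlaneContour


def write_spike_times(path, train: SpikeTrain) -> None:
    np.savetxt(path, train.times, fmt="%.9f")


def read_spike_times(path, epoch: tuple[float, float], state: str = "swa",
                     identity: str = "") -> SpikeTrain:
    times = np.atleast_1d(np.loadtxt(path, dtype=float))
    return SpikeTrain(times=times, epoch=epoch, state=state, identity=identity)


def write_signal(path, signal: SampledSignal) -> None:
    """Delimited samples plus a ``<path>.yaml`` sidecar with fs/channel."""
    path = Path(path)
    np.savetxt(path, signal.samples, fmt="%.8g")
    sidecar = {"fs_hz": float(signal.fs), "channel": signal.channel}
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_signal(path) -> SampledSignal:
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    samples = np.loadtxt(path, dtype=float)
    return SampledSignal(samples=samples, fs=float(sidecar["fs_hz"]),
                         channel=str(sidecar.get("channel", "ecog")))


def write_contours(path, contours: list[PlaneContour]) -> None:
    rows = []
    for c in contours:
        for order, (x, y) in enumerate(c.vertices):
            rows.append({"plane_id": c.plane_id, "order": order,
                         "x_um": x, "y_um": y, "bregma_mm": c.bregma_mm,
                         "lateral_dir": c.lateral_dir, "dorsal_dir": c.dorsal_dir})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contours(path) -> list[PlaneContour]:
    df = pd.read_csv(path, sep="\t")
    contours = []
    for pid, grp in df.groupby("plane_id", sort=False):
        grp = grp.sort_values("order")
        contours.append(PlaneContour(
            plane_id=str(pid),
            vertices=grp[["x_um", "y_um"]].to_numpy(),
            bregma_mm=float(grp["bregma_mm"].iloc[0]),
            lateral_dir=int(grp["lateral_dir"].iloc[0]),
            dorsal_dir=int(grp["dorsal_dir"].iloc[0]),
        ))
    return contours


def write_neurons(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_neurons(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
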