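"""On-disk formats: CSV traces with JSON sidecars, cohort manifests,
freezing-bout tables.

A sweep lives in two files: ``<stem>.csv`` with columns ``time_s,value``
and ``<stem>.json`` carrying units, sampling rate, clamp mode, stimulus
windows, pH, holding potential, and any generator metadata.  A cohort is
a directory with one sub-directory per cell and a ``manifest.json``
listing cells and their sweep stems.  Freezing sessions are CSVs of
``epoch_label,bout_start_s,bout_end_s`` (the epoch label column is
informational; scoring re-derives epoch membership from the protocol).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .behavior import Epoch, FreezingSession, ProtocolSpec
from .sweeps import SweepRecording

__all__ = [
    "write_sweep",
    "read_sweep",
    "write_cohort",
    "read_cohort",
    "write_freezing_session",
    "read_freezing_session",
    "write_protocol",
    "read_protocol",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sweep(sweep: SweepRecording, stem: Path) -> None:
    stem = Path(stem)
    pd.DataFrame({"time_s": sweep.time_s, "value": sweep.samples}).to_csv(
        stem.with_suffix(".csv"), index=False
    )
    sidecar = {
        "units": sweep.units,
        "clamp": sweep.clamp,
        "sampling_rate_khz": sweep.sampling_khz,
        "injected_pa": sweep.injected_pa,
        "step_window_s": sweep.step_window,
        "pulse_window_s": sweep.pulse_window,
        "ph": sweep.ph,
        "holding_mv": sweep.holding_mv,
        "meta": _jsonable(sweep.meta),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sweep(stem: Path) -> SweepRecording:
    stem = Path(stem)
    table = pd.read_csv(stem.with_suffix(".csv"))
    side = json.loads(stem.with_suffix(".json").read_text())
    return SweepRecording(
        time_s=table["time_s"].to_numpy(),
        samples=table["value"].to_numpy(),
        clamp=side["clamp"],
        sampling_khz=side["sampling_rate_khz"],
        injected_pa=side.get("injected_pa"),
        step_window=tuple(side["step_window_s"]) if side.get("step_window_s") else None,
        pulse_window=tuple(side["pulse_window_s"]) if side.get("pulse_window_s") else None,
        ph=side.get("ph"),
        holding_mv=side.get("holding_mv"),
        meta=side.get("meta", {}),
    )


def write_cohort(cells: Dict[str, Sequence[SweepRecording]], directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for cell_id, sweeps in cells.items():
        cell_dir = directory / cell_id
        cell_dir.mkdir(exist_ok=True)
        stems = []
        for i, sweep in enumerate(sweeps):
            stem = cell_dir / f"sweep{i:02d}"
            write_sweep(sweep, stem)
            stems.append(str(stem.relative_to(directory)))
        manifest[cell_id] = stems
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(directory: Path) -> Dict[str, List[SweepRecording]]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return {
        cell_id: [read_sweep(directory / stem) for stem in stems]
        for cell_id, stems in manifest.items()
    }


def write_freezing_session(session: FreezingSession, path: Path) -> None:
    rows = []
    for s, e in session.bouts:
        label = ""
        for epoch in session.protocol.epochs:
            if epoch.start_s <= s < epoch.end_s:
                label = epoch.label
                break
        rows.append({"epoch_label": label, "bout_start_s": s, "bout_end_s": e})
    pd.DataFrame(rows, columns=["epoch_label", "bout_start_s", "bout_end_s"]).to_csv(
        path, index=False
    )


def read_freezing_session(path: Path, protocol: ProtocolSpec) -> FreezingSession:
    table = pd.read_csv(path)
    bouts = list(zip(table["bout_start_s"].astype(float), table["bout_end_s"].astype(float)))
    return FreezingSession(protocol=protocol, bouts=bouts)


def write_protocol(protocol: ProtocolSpec, path: Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"label": e.label, "start_s": e.start_s, "end_s": e.end_s, "kind": e.kind}
                for e in protocol.epochs
            ],
            indent=1,
        )
    )


def read_protocol(path: Path) -> ProtocolSpec:
    spec = json.loads(Path(path).read_text())
    return ProtocolSpec([Epoch(e["label"], e["start_s"], e["end_s"], e["kind"]) for e in spec])
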