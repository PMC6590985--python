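"""Plain-text I/O: spike-train CSV bundles and stimulus CSVs with sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .types import SpikeTrain, StimulusTrace


def write_spike_trains_csv(trains: Sequence[SpikeTrain], path) -> None:
    """Tidy CSV ``unit_id,trial_id,spike_time_s`` plus a JSON metadata sidecar."""
    rows = []
    meta: Dict[str, dict] = {}
    for tr in trains:
        key = f"{tr.unit_id}/{tr.trial_id}"
        meta[key] = {
            "duration_s": tr.duration,
            "afferent_class": tr.afferent_class,
        }
        for t in tr.spike_times:
            rows.append((tr.unit_id, tr.trial_id, t))
    pd.DataFrame(rows, columns=["unit_id", "trial_id", "spike_time_s"]).to_csv(
        path, index=False
    )
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_spike_trains_csv(path) -> List[SpikeTrain]:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    out = []
    for (uid, tid), grp in df.groupby(["unit_id", "trial_id"], sort=True):
        m = meta[f"{uid}/{tid}"]
        out.append(
            SpikeTrain(
                np.sort(grp["spike_time_s"].to_numpy()),
                duration=m["duration_s"],
                unit_id=str(uid),
                trial_id=int(tid),
                afferent_class=m.get("afferent_class", "unknown"),
            )
        )
    return out


def write_stimulus_csv(stim: StimulusTrace, path) -> None:
    pd.DataFrame({"time_s": stim.times, "value": stim.values}).to_csv(
        path, index=False
    )
    sidecar = {"dt_s": stim.dt, "t0_s": stim.t0, "kind": stim.kind, **stim.meta}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_stimulus_csv(path) -> StimulusTrace:
    df = pd.read_csv(path)
    side = json.loads(Path(str(path) + ".json").read_text())
    kind = side.pop("kind", "acceleration")
    dt = side.pop("dt_s")
    t0 = side.pop("t0_s", 0.0)
    return StimulusTrace(df["value"].to_numpy(), dt=dt, t0=t0, kind=kind, meta=side)
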