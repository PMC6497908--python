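"""Plain-text I/O: CSV signal files, JSON schedule/events/results.

File formats (shared by the synthetic generator and the analysis):

* ``emg.csv`` — ``time_s`` plus one column per channel named
  ``<side>_<muscle>`` (sides ``left``/``right``).
* ``forces.csv`` — ``time_s, fz_left_N, fz_right_N``.
* ``markers.csv`` — ``time_s, ankle_left_ap_m, ankle_right_ap_m,
  hip_left_ap_m, hip_right_ap_m`` (anterior positive, meters).
* ``schedule.json`` — ordered conditions with belt speeds and realized
  block time spans.
* ``ground_truth.json`` — generator ground truth (events, betas,
  per-condition vectors) for synthetic trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_prep import GaitEvents, SampledSignal
from .synth import BlockSpan, SyntheticTrial


@dataclass
class SubjectRecord:
    """Pointer to one subject's files plus demographics."""

    subject_id: str
    age: float
    medium_speed: float
    dominant_side: str
    emg_path: str
    forces_path: str
    markers_path: str
    schedule_path: str

    def __post_init__(self) -> None:
        if self.age <= 0 or self.medium_speed <= 0:
            raise ValueError("age and medium_speed must be positive")


def write_signal_csv(signal: SampledSignal, path: str | Path) -> None:
    df = pd.DataFrame(signal.values, columns=signal.channels)
    df.insert(0, "time_s", signal.times)
    df.to_csv(path, index=False, float_format="%.6g")


def read_signal_csv(path: str | Path) -> SampledSignal:
    df = pd.read_csv(path)
    t = df.pop("time_s").to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    return SampledSignal(df.to_numpy(), round(rate, 6), list(df.columns), float(t[0]))


def write_schedule_json(blocks: list[BlockSpan], path: str | Path) -> None:
    payload = [
        {"condition": b.condition, "start_s": b.start_s, "stop_s": b.stop_s,
         "speeds_m_s": b.speeds}
        for b in blocks
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_schedule_json(path: str | Path) -> list[BlockSpan]:
    payload = json.loads(Path(path).read_text())
    return [BlockSpan(b["condition"], b["start_s"], b["stop_s"], b["speeds_m_s"])
            for b in payload]


def write_events_json(events: GaitEvents, path: str | Path) -> None:
    Path(path).write_text(json.dumps(events.to_dict(), indent=1))


def read_events_json(path: str | Path) -> GaitEvents:
    return GaitEvents.from_dict(json.loads(Path(path).read_text()))


def write_trial(trial: SyntheticTrial, out_dir: str | Path) -> None:
    """Write a synthetic trial in the pipeline's input formats.

    Continuous signals are large; prefer compact schedules when writing
    to disk.  ``ground_truth.json`` carries the generator's known
    events, betas, transition deltas and normalization map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_signal_csv(trial.emg, out / "emg.csv")
    write_signal_csv(trial.forces, out / "forces.csv")
    write_signal_csv(trial.markers, out / "markers.csv")
    write_schedule_json(trial.blocks, out / "schedule.json")
    gt = trial.ground_truth
    payload = {
        "events": gt.events.to_dict(),
        "betas": gt.betas,
        "transition_deltas": {k: v.tolist() for k, v in gt.transition_deltas.items()},
        "condition_steady": {k: v.tolist() for k, v in gt.condition_steady.items()},
        "normalization": gt.normalization.to_dict(),
        "stride_conditions": gt.stride_conditions,
        "sla": gt.sla.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))


def load_subject_data(record: SubjectRecord):
    """Read a subject's files into in-memory pipeline inputs."""
    from .pipeline import SubjectData

    return SubjectData(
        emg=read_signal_csv(record.emg_path),
        forces=read_signal_csv(record.forces_path),
        markers=read_signal_csv(record.markers_path),
        blocks=read_schedule_json(record.schedule_path),
    )


def write_subject_result(result, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = result.index.labels()
    for cond, mat in result.stride_matrices.items():
        pd.DataFrame(mat, columns=labels).to_csv(
            out / f"activity_{cond}.csv", index=False, float_format="%.5g")
    write_events_json(result.events, out / "events.json")
    payload = {
        "regressions": {k: v.to_dict() for k, v in result.regressions.items()},
        "cosines": result.cosines,
        "magnitudes": result.magnitudes,
        "deltas": {k: v.values.tolist() for k, v in result.deltas.items()},
        "normalization": {leg: m.to_dict() for leg, m in result.normalization.items()},
        "manifest": result.manifest,
    }
    (out / "results.json").write_text(json.dumps(payload, indent=1))


def write_group_result(group, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    group.tidy.to_csv(out / "group_tidy.csv", index=False)
    rows = []
    for name, (test, fdr) in group.epoch_maps.items():
        for j in range(test.p.size):
            rows.append({
                "contrast": name, "component": j, "effect": test.effect[j],
                "p": test.p[j], "significant": bool(fdr.reject[j]),
                "displayed": bool(test.displayed[j]),
            })
    if rows:
        pd.DataFrame(rows).to_csv(out / "component_maps.csv", index=False)
    payload = {
        "regressions": {k: v.to_dict() for k, v in group.regressions.items()},
        "cosines": group.cosines,
        "paired": {k: vars(v) for k, v in group.paired.items()},
        "correlations": {k: list(v) for k, v in group.correlations.items()},
        "fdr": {k: {"critical_p": fdr.critical_p, "n_rejected": fdr.n_rejected,
                    "m0_estimate": fdr.m0_estimate}
                for k, (_t, fdr) in group.epoch_maps.items()},
        "manifest": group.manifest,
    }
    (out / "group_results.json").write_text(json.dumps(payload, indent=1))
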