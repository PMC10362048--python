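"""Reading and writing study directories.

Layout::

    study/
      study.json                    # configs, seed, n_animals
      animal_<k>/
        session_<j>/
          events.csv                # time_s, event, port, trial_hint
          spikes.csv                # unit_id, time_s      (optional)
          meta.json                 # animal/session ids, configs reference
          truth.json                # planted ground truth (optional)

Times are seconds from session start at 1 ms precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AgentConfig, NeuronConfig, TaskConfig, config_dict
from .synthetic.agent import AgentPlan
from .synthetic.study import AnimalData, SessionData, SessionTruth, StudyData

__all__ = [
    "write_session", "read_session", "write_study", "read_study",
    "study_session_dirs",
]


def _clean(obj):
    """JSON-encode helper: tuples->lists, numpy scalars->python, NaN->None."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _truth_payload(truth: SessionTruth) -> dict:
    payload = {
        "session_index": truth.session_index,
        "d0": truth.d0,
        "d1": truth.d1,
        "d2": truth.d2,
        "transition_trial": truth.transition_trial,
        "trials": _clean(truth.trials.to_dict(orient="records")),
    }
    if truth.units is not None:
        payload["units"] = _clean(truth.units.to_dict(orient="records"))
    return payload


def _truth_from_payload(payload: dict) -> SessionTruth:
    return SessionTruth(
        session_index=int(payload["session_index"]),
        d0=int(payload["d0"]),
        d1=int(payload["d1"]),
        d2=int(payload["d2"]),
        transition_trial=int(payload["transition_trial"]),
        trials=pd.DataFrame(payload["trials"]),
        units=pd.DataFrame(payload["units"]) if "units" in payload else None,
    )


def write_session(session: SessionData, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ev = session.events.copy()
    ev["time_s"] = ev["time_s"].map(lambda v: f"{v:.3f}")
    ev.to_csv(path / "events.csv", index=False)
    if session.spikes is not None:
        sp = session.spikes.copy()
        sp["time_s"] = sp["time_s"].map(lambda v: f"{v:.3f}")
        sp.to_csv(path / "spikes.csv", index=False)
    meta = dict(meta or {})
    meta.setdefault("session_index", session.session_index)
    (path / "meta.json").write_text(json.dumps(_clean(meta), indent=1))
    if session.truth is not None:
        (path / "truth.json").write_text(json.dumps(_truth_payload(session.truth)))
    return path


def read_session(path) -> SessionData:
    path = Path(path)
    events = pd.read_csv(path / "events.csv")
    events["time_s"] = events["time_s"].astype(float)
    if "trial_hint" not in events.columns:
        events["trial_hint"] = -1
    spikes = None
    if (path / "spikes.csv").exists():
        spikes = pd.read_csv(path / "spikes.csv")
        spikes["time_s"] = spikes["time_s"].astype(float)
    truth = None
    if (path / "truth.json").exists():
        truth = _truth_from_payload(json.loads((path / "truth.json").read_text()))
    meta = {}
    if (path / "meta.json").exists():
        meta = json.loads((path / "meta.json").read_text())
    return SessionData(
        session_index=int(meta.get("session_index", -1)),
        events=events,
        spikes=spikes,
        truth=truth,
    )


def write_study(study: StudyData, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": study.seed,
        "n_animals": len(study.animals),
        "configs": config_dict(study.task, study.agent, study.neurons),
    }
    (out / "study.json").write_text(json.dumps(_clean(manifest), indent=1))
    for k, animal in enumerate(study.animals):
        for sess in animal.sessions:
            meta = {
                "animal_id": animal.animal_id,
                "session_index": sess.session_index,
            }
            if animal.plan is not None:
                meta["plan"] = dataclasses.asdict(animal.plan)
            write_session(
                sess,
                out / f"animal_{k}" / f"session_{sess.session_index}",
                meta=meta,
            )
    return out


def study_session_dirs(study_dir) -> dict[str, list[Path]]:
    """Map animal directory name -> ordered session directories."""
    study_dir = Path(study_dir)
    out: dict[str, list[Path]] = {}
    for adir in sorted(study_dir.glob("animal_*"), key=lambda p: p.name):
        sessions = sorted(
            adir.glob("session_*"), key=lambda p: int(p.name.split("_")[1])
        )
        out[adir.name] = sessions
    return out


def read_study(study_dir) -> StudyData:
    study_dir = Path(study_dir)
    manifest = {}
    if (study_dir / "study.json").exists():
        manifest = json.loads((study_dir / "study.json").read_text())
    cfgs = manifest.get("configs", {})

    def build(cls, name):
        raw = cfgs.get(name)
        if raw is None:
            return cls()
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.items()
            if k in fields
        }
        return cls(**kwargs)

    animals = []
    for name, sess_dirs in study_session_dirs(study_dir).items():
        sessions = [read_session(d) for d in sess_dirs]
        plan = None
        if sessions:
            meta = json.loads((sess_dirs[0] / "meta.json").read_text())
            if "plan" in meta:
                plan = AgentPlan(**meta["plan"])
        animals.append(AnimalData(animal_id=name, plan=plan, sessions=sessions))
    return StudyData(
        animals=animals,
        task=build(TaskConfig, "TaskConfig"),
        agent=build(AgentConfig, "AgentConfig"),
        neurons=build(NeuronConfig, "NeuronConfig"),
        seed=manifest.get("seed"),
    )
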