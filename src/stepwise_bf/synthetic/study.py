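"""Whole-study simulation: independent agents, sessions and spike tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import AgentConfig, NeuronConfig, TaskConfig
from .agent import AgentPlan, simulate_session
from .spikes import simulate_spikes

__all__ = ["SessionTruth", "SessionData", "AnimalData", "StudyData", "simulate_study"]


@dataclass
class SessionTruth:
    """Planted ground truth for one session."""

    session_index: int
    d0: int
    d1: int
    d2: int
    transition_trial: int
    trials: pd.DataFrame
    units: pd.DataFrame | None = None

    @property
    def merged(self) -> bool:
        return self.d1 == self.d2


@dataclass
class SessionData:
    session_index: int
    events: pd.DataFrame
    spikes: pd.DataFrame | None = None
    truth: SessionTruth | None = None


@dataclass
class AnimalData:
    animal_id: str
    plan: AgentPlan | None
    sessions: list[SessionData] = field(default_factory=list)


@dataclass
class StudyData:
    animals: list[AnimalData]
    task: TaskConfig
    agent: AgentConfig
    neurons: NeuronConfig
    seed: int | None = None


def simulate_study(
    task: TaskConfig,
    agent: AgentConfig,
    neurons: NeuronConfig,
    n_animals: int,
    seed: int,
    out_dir=None,
    with_spikes: bool = True,
) -> StudyData:
    """Simulate ``n_animals`` independent agents through the new-learning
    phase.

    Each animal uses a deterministic sub-stream derived from ``seed`` and its
    ordinal, so the study is reproducible given the seed and any animal can
    be regenerated in isolation.  If ``out_dir`` is given the study is also
    written as a directory of session bundles (see :mod:`stepwise_bf.io`).
    """
    animals: list[AnimalData] = []
    for k in range(n_animals):
        rng = np.random.default_rng(int(seed) + k)
        plan = AgentPlan.sample(agent, rng)
        animal = AnimalData(animal_id=f"animal_{k}", plan=plan)
        for s in range(agent.n_sessions):
            events, trials = simulate_session(task, agent, s, rng, plan=plan)
            truth = SessionTruth(
                session_index=s, d0=plan.d0, d1=plan.d1, d2=plan.d2,
                transition_trial=plan.transition_trial, trials=trials,
            )
            spikes = None
            if with_spikes:
                spikes, units = simulate_spikes(
                    events, trials, neurons, rng, session_index=s, d2=plan.d2
                )
                truth.units = units
            animal.sessions.append(
                SessionData(session_index=s, events=events, spikes=spikes, truth=truth)
            )
        animals.append(animal)

    study = StudyData(animals=animals, task=task, agent=agent, neurons=neurons, seed=seed)
    if out_dir is not None:
        from .. import io

        io.write_study(study, out_dir)
    return study
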