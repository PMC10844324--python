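"""Synthetic Libet-clock experiment: design, ideal observers, trial tables.

Reproduces the study design used for parameter and model recovery:
two baseline blocks (action-only keypress, tone-only) and two operant
blocks (report the keypress / report the tone) crossed with three
action-outcome intervals, 60 trials per condition cell, 480 trials per
observer.  Baseline reports are the raw percepts; operant reports come
from an observer model's decision rule.

Trial tables are pandas DataFrames with columns
(observer_id, task, target, t_AO, report, error); ``error`` is the
report minus the actual target time (0 for action targets, t_AO for
outcome targets), so baseline error distributions directly estimate
the sensory bias/noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    DEFAULT_BASELINES,
    PARAM_BOUNDS,
    FreeParams,
    ModelSpec,
    ObserverParams,
    get_model,
    respond,
    sample_percepts,
)

__all__ = [
    "TRIAL_COLUMNS",
    "DesignSpec",
    "TrialRecord",
    "SimulatedDataset",
    "sample_free_params",
    "simulate_observer",
    "simulate_cohort",
    "write_trials",
    "read_trials",
]

TRIAL_COLUMNS = ["observer_id", "task", "target", "t_AO", "report", "error"]


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: condition cells and their trial counts."""

    intervals: tuple[float, ...] = (0.0, 250.0, 500.0)
    trials_per_condition: int = 60
    n_observers: int = 76

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if len(self.intervals) == 0:
            raise ValueError("design needs at least one operant interval")

    def cells(self) -> list[tuple[str, str, float]]:
        """(task, target, t_AO) for every condition cell, in canonical order."""
        cells = [("baseline", "action", 0.0), ("baseline", "outcome", 0.0)]
        for target in ("action", "outcome"):
            for interval in self.intervals:
                cells.append(("operant", target, float(interval)))
        return cells

    @property
    def trials_per_observer(self) -> int:
        return len(self.cells()) * self.trials_per_condition


@dataclass(frozen=True)
class TrialRecord:
    """One time-estimation trial in the operant (action-at-zero) frame."""

    observer_id: str
    task: str
    target: str
    t_AO: float
    report: float
    error: float


@dataclass
class SimulatedDataset:
    """Trials simulated from one generating model for one observer."""

    model_id: str
    free: FreeParams
    params: ObserverParams
    seed: object
    trials: pd.DataFrame = field(repr=False)


def sample_free_params(
    model: str | ModelSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> FreeParams:
    """Draw a model's free parameters uniformly from their stated ranges."""
    model = get_model(model)
    if model.n_free == 0:
        raise ValueError(f"model {model.id} has no free parameters to sample")
    rng = np.random.default_rng(seed)
    values = {
        name: rng.uniform(*PARAM_BOUNDS[name]) for name in model.free_param_names
    }
    return FreeParams(**values)


def _actual_time(target: str, t_AO: float) -> float:
    return 0.0 if target == "action" else t_AO


def simulate_observer(
    model: str | ModelSpec,
    free: FreeParams,
    params: ObserverParams = DEFAULT_BASELINES,
    design: DesignSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    observer_id: str = "obs0",
) -> SimulatedDataset:
    """Simulate one ideal observer's full session.

    Baseline trials report the raw percept of the single event; operant
    trials report the model's decision-rule output.  Each condition cell
    draws from its own child RNG stream spawned from ``seed``, so any
    cell is reproducible independently of the others.
    """
    model = get_model(model)
    model.validate_free(free)
    design = design or DesignSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cells = design.cells()
    children = ss.spawn(len(cells))
    n = design.trials_per_condition

    frames = []
    for (task, target, t_AO), child in zip(cells, children):
        rng = np.random.default_rng(child)
        pp = sample_percepts(params, t_AO, n, rng)
        if task == "baseline":
            report = np.asarray(pp.tau_A if target == "action" else pp.tau_O)
        else:
            u = rng.uniform(size=n)
            report = respond(model, free, pp, params, target, u)
        actual = _actual_time(target, t_AO)
        frames.append(
            pd.DataFrame(
                {
                    "observer_id": observer_id,
                    "task": task,
                    "target": target,
                    "t_AO": t_AO,
                    "report": report,
                    "error": report - actual,
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return SimulatedDataset(model.id, free, params, ss.entropy, trials)


def simulate_cohort(
    model: str | ModelSpec,
    design: DesignSpec | None = None,
    params: ObserverParams = DEFAULT_BASELINES,
    seed: int = 0,
    free: FreeParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of observers under one generating model.

    When ``free`` is None, each observer's free parameters are drawn
    independently from the uniform ranges (the recovery-study setting);
    otherwise every observer shares the given values.  Returns the
    concatenated trial table and a per-observer table of the generating
    parameter values.
    """
    model = get_model(model)
    design = design or DesignSpec()
    ss = np.random.SeedSequence(seed)
    trials, truths = [], []
    for i, child in enumerate(ss.spawn(design.n_observers)):
        param_seed, sim_seed = child.spawn(2)
        if free is not None:
            free_i = free
        elif model.n_free:
            free_i = sample_free_params(model, param_seed)
        else:
            free_i = FreeParams()
        observer_id = f"{model.id}_{i:03d}"
        ds = simulate_observer(model, free_i, params, design, sim_seed, observer_id)
        trials.append(ds.trials)
        truths.append({"observer_id": observer_id, "model": model.id, **free_i.as_dict()})
    return pd.concat(trials, ignore_index=True), pd.DataFrame(truths)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with header; round-trips losslessly."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    trials = pd.read_csv(
        path,
        dtype={
            "observer_id": str,
            "task": str,
            "target": str,
            "t_AO": float,
            "report": float,
            "error": float,
        },
    )
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    return trials[TRIAL_COLUMNS]
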