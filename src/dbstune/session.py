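"""Visit schedulers: the brute-force sweep and the Bayesian-optimization session.

Visit 1 (brute force) measures RoMaR at every grid frequency from 10 to
185 Hz in 5 Hz steps in seeded pseudorandom order, book-ended by two
measurements at the patient's clinical frequency. Visit 2 (BayesOpt)
measures four seed frequencies (30, 80, 90, 140 Hz), freezes the GP's
constant mean at their average, then runs eight acquisition iterations:
refit hyperparameters, predict on the feasible grid, select the
expected-improvement argmax (with the exploration override), measure, and
ask the patient whether they prefer the current or the previous setting.
A full session therefore yields 12 rigidity measurements and 11 pairwise
preference choices.

An intolerable frequency (the patient's ceiling) removes that frequency and
all higher ones from the grid; the iteration re-selects rather than being
consumed, matching the protocol's incorporation of boundaries discovered
earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import select_next_frequency
from .data import Observation, ObservationSet
from .exceptions import (
    IntolerableFrequencyError,
    InvalidParameterError,
    NoFeasibleFrequencyError,
)
from .gp import RigidityGP, RigidityGPResults
from .preference import PreferenceDataset

__all__ = [
    "SessionConfig",
    "SessionState",
    "brute_force_schedule",
    "run_brute_force",
    "run_session",
]

DEFAULT_SEEDS = (30.0, 80.0, 90.0, 140.0)


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of a visit-2 optimization session."""

    seeds: tuple = DEFAULT_SEEDS
    iterations: int = 8
    step: float = 5.0
    fmin: float = 10.0
    fmax: float = 185.0
    ceiling: float | None = None  # boundary known from visit 1, if any
    exploration_ratio: float = 0.5
    gp_restarts: int = 8
    pgp_restarts: int = 25
    preference_enabled: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        errors = []
        if self.step <= 0:
            errors.append("step")
        if self.fmin > self.fmax:
            errors.append("fmin/fmax")
        if self.iterations < 0:
            errors.append("iterations")
        if self.exploration_ratio < 0:
            errors.append("exploration_ratio")
        if self.step > 0:
            for f in self.seeds:
                offset = (f - self.fmin) / self.step
                if abs(offset - round(offset)) > 1e-9 or not (
                    self.fmin - 1e-9 <= f <= self.fmax + 1e-9
                ):
                    errors.append(f"seeds[{f}]")
        if errors:
            raise InvalidParameterError(
                f"invalid session configuration fields: {errors}"
            )

    def replace(self, **kwargs) -> "SessionConfig":
        return replace(self, **kwargs)

    def grid(self, ceiling: float | None = None) -> np.ndarray:
        """Candidate grid from fmin up to the effective ceiling."""
        top = min(x for x in (self.fmax, self.ceiling, ceiling) if x is not None)
        return np.arange(self.fmin, top + self.step / 2, self.step)


@dataclass
class SessionState:
    """Everything a session produced, sufficient to refit all models offline."""

    config: SessionConfig
    history: ObservationSet = field(default_factory=ObservationSet)
    preferences: PreferenceDataset = field(default_factory=PreferenceDataset)
    ceiling: float | None = None
    mean_const: float | None = None
    model: RigidityGPResults | None = None
    events: list = field(default_factory=list)
    status: str = "complete"


def brute_force_schedule(
    fmin: float = 10.0,
    fmax: float = 185.0,
    step: float = 5.0,
    clinical_freq: float | None = None,
    rng=None,
) -> list[float]:
    """Grid frequencies in seeded pseudorandom order, book-ended by the
    clinical frequency (one measurement before and one after) when given."""
    if fmin > fmax:
        raise InvalidParameterError("fmin must not exceed fmax")
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    n_steps = (fmax - fmin) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidParameterError("step must divide (fmax - fmin)")
    grid = fmin + step * np.arange(int(round(n_steps)) + 1)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = list(rng.permutation(grid))
    if clinical_freq is not None:
        order = [float(clinical_freq)] + order + [float(clinical_freq)]
    return [float(f) for f in order]


def run_brute_force(
    patient,
    fmin: float = 10.0,
    fmax: float = 185.0,
    step: float = 5.0,
    clinical_freq: float | None = None,
    rng_seed: int = 0,
) -> tuple[ObservationSet, float]:
    """Execute the visit-1 sweep against a patient.

    On an intolerable frequency the ceiling drops just below it and every
    untested frequency above the new ceiling is skipped. Returns the
    observations and the final ceiling (fmax if never hit).
    """
    ss = np.random.SeedSequence(rng_seed)
    rng_order, rng_meas = [np.random.default_rng(s) for s in ss.spawn(2)]
    schedule = brute_force_schedule(fmin, fmax, step, clinical_freq, rng_order)
    obs = ObservationSet()
    ceiling = fmax
    for i, f in enumerate(schedule):
        if f > ceiling + 1e-9:
            continue
        # only the book-end entries are the clinical repeats, even when the
        # clinical frequency also belongs to the sweep grid
        source = (
            "clinical_repeat"
            if clinical_freq is not None and i in (0, len(schedule) - 1)
            else "brute_force"
        )
        try:
            y = patient.measure_romar(f, rng_meas)
        except IntolerableFrequencyError:
            ceiling = f - step
            continue
        obs.append(Observation(f, y, len(obs), source))
    return obs, float(ceiling)


def _fit_on_history(history: ObservationSet, mean_const: float, config: SessionConfig,
                    seed: int) -> RigidityGPResults:
    model = RigidityGP(history.x, history.y, mean_const=mean_const)
    return model.fit(restarts=config.gp_restarts, seed=seed)


def run_session(patient, config: SessionConfig | None = None) -> SessionState:
    """Run a complete visit-2 optimization session against a patient.

    ``patient`` is anything with ``measure_romar(f, rng)`` and (when
    preferences are enabled) ``choose_preference(f_current, f_previous,
    rng)`` — a ``VirtualPatient`` or an interactive operator adapter.

    All randomness flows from ``config.rng_seed`` through named child
    streams (measurement, choices, hyperparameter restarts), so the same
    patient and seed reproduce a bitwise-identical session.
    """
    config = config or SessionConfig()
    ss = np.random.SeedSequence(config.rng_seed)
    rng_meas, rng_pref, ss_fit = ss.spawn(3)
    rng_meas = np.random.default_rng(rng_meas)
    rng_pref = np.random.default_rng(rng_pref)
    fit_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_fit.spawn(config.iterations + 1)]

    state = SessionState(config=config, ceiling=config.ceiling or config.fmax)

    def measure(f: float, source: str) -> float:
        y = patient.measure_romar(f, rng_meas)
        state.history.append(Observation(f, y, len(state.history), source))
        if config.preference_enabled and len(state.history) >= 2:
            prev = state.history.observations[-2].x
            pair = patient.choose_preference(f, prev, rng_pref)
            pair = replace(pair, step_index=len(state.history) - 1)
            state.preferences.append(pair)
        return y

    try:
        for f in config.seeds:
            measure(float(f), "seed")
        state.mean_const = float(np.mean(state.history.y))

        for it in range(config.iterations):
            while True:
                results = _fit_on_history(
                    state.history, state.mean_const, config, fit_seeds[it]
                )
                acq = select_next_frequency(
                    results,
                    config.grid(state.ceiling),
                    ceiling=state.ceiling,
                    exploration_ratio=config.exploration_ratio,
                )
                try:
                    measure(acq.x_next, "bayesopt")
                except IntolerableFrequencyError:
                    state.ceiling = acq.x_next - config.step
                    state.events.append(
                        {"event": "intolerable", "frequency_hz": acq.x_next,
                         "new_ceiling_hz": state.ceiling, "iteration": it}
                    )
                    if config.grid(state.ceiling).size == 0:
                        raise NoFeasibleFrequencyError(
                            "ceiling fell below the whole candidate grid"
                        )
                    continue
                state.events.append(
                    {"event": "measurement", "iteration": it,
                     "frequency_hz": acq.x_next,
                     "utility_argmax": float(np.max(acq.utility)),
                     "overexploit_flag": acq.overexploit_flag,
                     "ceiling_hz": state.ceiling}
                )
                break

        state.model = _fit_on_history(
            state.history, state.mean_const, config, fit_seeds[config.iterations]
        )
        state.status = "complete"
    except KeyboardInterrupt:
        state.status = "aborted"
    return state
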