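"""Event-related experimental designs.

A jittered event-related design: fixed-duration stimuli separated by a
fixed inter-trial interval plus a uniform jitter. The design drives the
external-stimulus vector u(t) and the modulatory input v(t) of the latent
dynamics, both sampled on the TR grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EventDesign", "generate_event_design"]


@dataclass(frozen=True)
class EventDesign:
    """Trial onsets/durations/conditions for one run.

    Times are seconds from run start. Invariants: onsets strictly
    increasing, positive durations, every trial ends within ``run_length``.
    """

    trial_onsets: np.ndarray
    trial_durations: np.ndarray
    trial_conditions: np.ndarray
    run_length: float
    tr: float

    def __post_init__(self):
        onsets = np.asarray(self.trial_onsets, dtype=float)
        durs = np.asarray(self.trial_durations, dtype=float)
        conds = np.asarray(self.trial_conditions)
        if onsets.ndim != 1 or len(onsets) != len(durs) or len(onsets) != len(conds):
            raise ValueError("onsets, durations, conditions must be 1-D and equal length")
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        if np.any(durs <= 0):
            raise ValueError("trial durations must be positive")
        if len(onsets) and np.any(onsets + durs > self.run_length + 1e-9):
            raise ValueError("every trial must end within run_length")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        object.__setattr__(self, "trial_onsets", onsets)
        object.__setattr__(self, "trial_durations", durs)
        object.__setattr__(self, "trial_conditions", conds)

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)

    @property
    def n_timepoints(self) -> int:
        return int(np.floor(self.run_length / self.tr))

    def boxcar(self, n_timepoints: int | None = None) -> np.ndarray:
        """Task-on indicator on the TR grid: 1 while any stimulus is on."""
        n = n_timepoints if n_timepoints is not None else self.n_timepoints
        t = np.arange(n) * self.tr
        on = np.zeros(n)
        for onset, dur in zip(self.trial_onsets, self.trial_durations):
            on[(t >= onset) & (t < onset + dur)] = 1.0
        return on

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame({
            "onset": self.trial_onsets,
            "duration": self.trial_durations,
            "trial_type": self.trial_conditions,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, run_length: float, tr: float) -> "EventDesign":
        return cls(
            trial_onsets=df["onset"].to_numpy(float),
            trial_durations=df["duration"].to_numpy(float),
            trial_conditions=df["trial_type"].to_numpy(),
            run_length=run_length,
            tr=tr,
        )


def generate_event_design(
    n_trials: int = 52,
    stim_duration: float = 5.0,
    iti_fixed: float = 1.0,
    jitter_bounds: tuple[float, float] = (0.0, 3.5),
    tr: float = 2.0,
    seed: int | np.random.Generator | None = 0,
    initial_rest: float = 10.0,
    final_rest: float = 20.0,
    condition: str = "task",
) -> EventDesign:
    """Generate a jittered event-related design.

    Defaults mirror the study conditions: 52 trials of 5 s stimuli, a 1 s
    fixed inter-trial interval and a uniform 0-3.5 s jitter. Consecutive
    onset gaps equal ``stim_duration + iti_fixed + jitter`` with the jitter
    drawn i.i.d. Uniform(jitter_bounds). Deterministic for a fixed seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if stim_duration <= 0:
        raise ValueError("stim_duration must be positive")
    lo, hi = jitter_bounds
    if lo < 0 or hi < lo:
        raise ValueError("jitter_bounds must satisfy 0 <= low <= high")
    if iti_fixed < 0:
        raise ValueError("iti_fixed must be non-negative")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(lo, hi, size=n_trials - 1) if n_trials > 1 else np.array([])
    gaps = stim_duration + iti_fixed + jitter
    onsets = initial_rest + np.concatenate([[0.0], np.cumsum(gaps)])
    run_length = onsets[-1] + stim_duration + final_rest
    return EventDesign(
        trial_onsets=onsets,
        trial_durations=np.full(n_trials, stim_duration),
        trial_conditions=np.array([condition] * n_trials),
        run_length=run_length,
        tr=tr,
    )
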