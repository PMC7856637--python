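"""Stimulus timing for the overt word-generation paradigm.

The default paradigm is six runs of ten trials each (60 trials total): a 6.8 s
trial in which the participant hears/reads a category cue and generates a word
aloud, followed by a fixation inter-trial interval jittered between 13.6, 15.3
and 17 s.  Volumes are acquired at TR = 1.7 s, 186 per run, with the first nine
discarded to reach magnetization equilibrium.  All onsets are expressed in
seconds from the first *retained* frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusSchedule", "ScheduleOverflowError", "make_schedule"]


class ScheduleOverflowError(ValueError):
    """Raised when the requested trials do not fit in the run duration."""


@dataclass(frozen=True)
class StimulusSchedule:
    """Timing of one experimental session (possibly several runs).

    Onsets are seconds from the first retained frame of each run; the
    onset-to-onset gap is always ``trial_len_s`` plus one of ``iti_choices_s``.
    """

    n_runs: int
    trials_per_run: int
    trial_len_s: float
    iti_choices_s: tuple[float, ...]
    tr_s: float
    n_volumes: int
    n_discard: int
    onsets_s: tuple[tuple[float, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if any(iti <= 0 for iti in self.iti_choices_s):
            raise ValueError("ITIs must be positive")
        if min(self.n_runs, self.trials_per_run, self.n_volumes, self.n_discard) < 0:
            raise ValueError("counts must be non-negative")
        for onsets in self.onsets_s:
            arr = np.asarray(onsets)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError("onsets must be strictly increasing within a run")
            if arr.size and arr[-1] + self.trial_len_s > self.run_duration_s + 1e-9:
                raise ScheduleOverflowError(
                    f"trial ending at {arr[-1] + self.trial_len_s:.2f}s exceeds "
                    f"run duration {self.run_duration_s:.2f}s"
                )

    @property
    def n_frames(self) -> int:
        """Retained frames per run."""
        return self.n_volumes - self.n_discard

    @property
    def run_duration_s(self) -> float:
        return self.n_frames * self.tr_s

    @property
    def total_trials(self) -> int:
        return sum(len(o) for o in self.onsets_s)

    @property
    def mean_trial_spacing_s(self) -> float:
        """Mean onset-to-onset interval: trial length plus mean ITI."""
        return self.trial_len_s + float(np.mean(self.iti_choices_s))

    @property
    def task_freq_hz(self) -> float:
        """Nominal task frequency, 1 / mean onset-to-onset interval."""
        return 1.0 / self.mean_trial_spacing_s

    def onset_frames(self, run_index: int) -> np.ndarray:
        """Frame index of each onset in a run (floor of onset / TR)."""
        return np.floor(
            np.asarray(self.onsets_s[run_index], dtype=float) / self.tr_s
        ).astype(int)


def make_schedule(
    n_runs: int = 6,
    trials_per_run: int = 10,
    trial_len_s: float = 6.8,
    iti_choices_s: tuple[float, ...] = (13.6, 15.3, 17.0),
    tr_s: float = 1.7,
    n_volumes: int = 186,
    n_discard: int = 9,
    seed: int | None = 0,
    first_onset_s: float | None = None,
) -> StimulusSchedule:
    """Draw a jittered stimulus schedule.

    ITIs are drawn uniformly from ``iti_choices_s`` with the given seed.  The
    first onset defaults to seven TRs after the first retained frame so that
    the baseline-scaling window precedes all trials.

    Raises
    ------
    ScheduleOverflowError
        If any trial would extend past the end of the run.
    """
    rng = np.random.default_rng(seed)
    if first_onset_s is None:
        first_onset_s = 7 * tr_s
    run_duration = (n_volumes - n_discard) * tr_s
    onsets_all: list[tuple[float, ...]] = []
    for _ in range(n_runs):
        onsets: list[float] = []
        t = first_onset_s
        for _trial in range(trials_per_run):
            if t + trial_len_s > run_duration + 1e-9:
                raise ScheduleOverflowError(
                    f"{trials_per_run} trials do not fit in "
                    f"{run_duration:.1f}s of retained data"
                )
            onsets.append(round(t, 6))
            iti = float(rng.choice(iti_choices_s))
            t = t + trial_len_s + iti
        onsets_all.append(tuple(onsets))
    return StimulusSchedule(
        n_runs=n_runs,
        trials_per_run=trials_per_run,
        trial_len_s=trial_len_s,
        iti_choices_s=tuple(iti_choices_s),
        tr_s=tr_s,
        n_volumes=n_volumes,
        n_discard=n_discard,
        onsets_s=tuple(onsets_all),
    )
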