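"""Auditory oddball design: stimulus pairings, trial sequences, run schedules.

The paradigm presents trials of eight sounds (50 ms each, 700 ms
inter-stimulus interval): seven repetitions of a *standard* and one
*deviant* that may occur at position four, five, or six.  Because the
deviant occurs exactly once per trial and listeners know this, the
conditional probability of a deviant follows a hazard over the remaining
allowed slots: 1/3 at position four, 1/2 at position five (given no
deviant yet), and 1 at position six.  Two amplitude models summarise the
competing hypotheses about the neural response to each sound:

* ``h1`` (habituation): responses to repeated standards decay as 1/n and
  recover slightly after the deviant; deviants always respond fully.
* ``h2`` (prediction error): each sound responds in proportion to the
  probability of hearing it at that position, so responses track
  predictability rather than repetition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "StimulusPairing",
    "TrialSequence",
    "AmplitudeModel",
    "RunParams",
    "RunSchedule",
    "build_stimulus_pairings",
    "predictability",
    "h1_amplitudes",
    "h2_amplitudes",
    "amplitude_model",
    "build_run",
    "event_table",
    "write_events",
    "read_events",
    "default_pure_tones",
    "default_fm_sweeps",
]

SOUND_DURATION = 0.050
ISI = 0.700
SOA = SOUND_DURATION + ISI          # onset-to-onset spacing within a trial
N_SOUNDS = 8
TRIAL_DURATION = (N_SOUNDS - 1) * SOA + SOUND_DURATION   # 5.30 s
DEVIANT_POSITIONS = (4, 5, 6)
CONDITIONS = ("std0", "std1", "std2", "dev4", "dev5", "dev6")


@dataclass(frozen=True)
class Stimulus:
    """One of the three sounds used to build oddball sequences.

    Pure tones are described by their frequency; FM-sweeps by their
    frequency span (end minus start frequency, signed).
    """

    label: str
    kind: str                      # "pure_tone" | "fm_sweep"
    frequency_hz: float | None = None
    span_hz: float | None = None

    def feature(self) -> float:
        if self.kind == "pure_tone":
            if self.frequency_hz is None:
                raise ValueError(f"pure tone {self.label!r} needs frequency_hz")
            return float(self.frequency_hz)
        if self.kind == "fm_sweep":
            if self.span_hz is None:
                raise ValueError(f"FM-sweep {self.label!r} needs span_hz")
            return float(self.span_hz)
        raise ValueError(f"unknown stimulus kind {self.kind!r}")


@dataclass(frozen=True)
class StimulusPairing:
    """Ordered standard/deviant combination with its feature distance Δ.

    Δ = |f_std − f_dev| for pure tones and |Δf_dev − Δf_std| for sweeps.
    """

    standard: Stimulus
    deviant: Stimulus

    def __post_init__(self) -> None:
        if self.standard.label == self.deviant.label:
            raise ValueError("a stimulus cannot be paired with itself")
        if self.standard.kind != self.deviant.kind:
            raise ValueError("standard and deviant must be of the same kind")

    @property
    def kind(self) -> str:
        return self.standard.kind

    @property
    def delta(self) -> float:
        return abs(self.deviant.feature() - self.standard.feature())

    @property
    def name(self) -> str:
        return f"{self.standard.label}->{self.deviant.label}"


def default_pure_tones() -> list[Stimulus]:
    """The three pure tones (1455, 1500, 1600 Hz; Δ ∈ {145, 100, 45} Hz)."""
    return [
        Stimulus("t1455", "pure_tone", frequency_hz=1455.0),
        Stimulus("t1500", "pure_tone", frequency_hz=1500.0),
        Stimulus("t1600", "pure_tone", frequency_hz=1600.0),
    ]


def default_fm_sweeps() -> list[Stimulus]:
    """The three FM-sweeps: 1000→1080, 1070→1170, 1280→1200 Hz.

    Spans are signed (+80, +100, −80 Hz); pairings are characterised by
    the absolute span difference.
    """
    return [
        Stimulus("s1000_1080", "fm_sweep", span_hz=80.0),
        Stimulus("s1070_1170", "fm_sweep", span_hz=100.0),
        Stimulus("s1280_1200", "fm_sweep", span_hz=-80.0),
    ]


def build_stimulus_pairings(stimuli: Sequence[Stimulus]) -> list[StimulusPairing]:
    """All six ordered standard/deviant pairings of three distinct stimuli."""
    if len(stimuli) != 3:
        raise ValueError(f"need exactly 3 stimuli, got {len(stimuli)}")
    if len({s.label for s in stimuli}) != 3:
        raise ValueError("stimuli must be distinct")
    if len({s.kind for s in stimuli}) != 1:
        raise ValueError("stimuli must all be of the same kind")
    return [
        StimulusPairing(std, dev)
        for std in stimuli for dev in stimuli if std.label != dev.label
    ]


def predictability(position: int, deviant_position: int,
                   exact: bool = False) -> float | Fraction:
    """Probability of hearing the sound actually presented at ``position``.

    The probability conditions on all preceding sounds of the trial.  At
    the candidate positions 4–6 the deviant hazard is 1 over the number
    of remaining allowed slots (1/3, then 1/2, then 1); the standard at
    those positions occurs with the complementary probability.  The very
    first sound is assigned 1/2: either member of the pairing may open
    the trial.  Standards at positions where no deviant is possible (or
    after the deviant already occurred) are fully predictable (P = 1).
    """
    if deviant_position not in DEVIANT_POSITIONS:
        raise ValueError(f"deviant_position must be in {DEVIANT_POSITIONS}")
    if not 1 <= position <= N_SOUNDS:
        raise ValueError(f"position must be in 1..{N_SOUNDS}")
    if position == 1:
        p = Fraction(1, 2)
    elif position < 4 or position > deviant_position:
        p = Fraction(1)                       # deviant impossible / already heard
    else:
        hazard = Fraction(1, 7 - position)    # 1/3, 1/2, 1 at positions 4, 5, 6
        p = hazard if position == deviant_position else 1 - hazard
    return p if exact else float(p)


def h1_amplitudes(deviant_position: int, exact: bool = False) -> np.ndarray | tuple:
    """Habituation-model amplitude profile for one trial.

    The first standard and the deviant respond fully (amplitude 1); the
    n-th standard of the trial (counting standards only, the first being
    n = 1) responds 1/n before the deviant and, reflecting a slight
    post-deviant recovery, 1/(n − 1) after it.
    """
    if deviant_position not in DEVIANT_POSITIONS:
        raise ValueError(f"deviant_position must be in {DEVIANT_POSITIONS}")
    amps = []
    n_std = 0
    for pos in range(1, N_SOUNDS + 1):
        if pos == deviant_position:
            amps.append(Fraction(1))
            continue
        n_std += 1
        if pos < deviant_position:
            amps.append(Fraction(1, n_std))
        else:
            amps.append(Fraction(1, n_std - 1))
    return tuple(amps) if exact else np.array([float(a) for a in amps])


def h2_amplitudes(deviant_position: int, exact: bool = False) -> np.ndarray | tuple:
    """Prediction-error-model amplitudes: the predictability of each sound."""
    amps = tuple(predictability(pos, deviant_position, exact=True)
                 for pos in range(1, N_SOUNDS + 1))
    return amps if exact else np.array([float(a) for a in amps])


@dataclass(frozen=True)
class AmplitudeModel:
    """Named per-position amplitude vectors, one per deviant position."""

    name: str
    amplitudes: dict[int, np.ndarray]

    def trial_amplitudes(self, deviant_position: int) -> np.ndarray:
        return self.amplitudes[deviant_position]


def amplitude_model(name: str) -> AmplitudeModel:
    """Build the ``h1`` (habituation) or ``h2`` (prediction error) model."""
    if name == "h1":
        fn = h1_amplitudes
    elif name == "h2":
        fn = h2_amplitudes
    else:
        raise ValueError(f"unknown amplitude model {name!r}")
    return AmplitudeModel(name, {d: fn(d) for d in DEVIANT_POSITIONS})


def _condition_labels(deviant_position: int) -> tuple[str, ...]:
    labels = []
    for pos in range(1, N_SOUNDS + 1):
        if pos == 1:
            labels.append("std0")
        elif pos == deviant_position:
            labels.append(f"dev{deviant_position}")
        elif pos < deviant_position:
            labels.append("std1")
        else:
            labels.append("std2")
    return tuple(labels)


@dataclass(frozen=True)
class TrialSequence:
    """One 8-sound trial: pairing, deviant position, labels, predictability.

    ``modulators`` holds the within-trial index of each repeated standard
    (1..count for std1 and again 1..count for std2); 0 elsewhere.
    """

    pairing: StimulusPairing
    deviant_position: int
    condition_labels: tuple[str, ...] = field(init=False)
    predictabilities: tuple[float, ...] = field(init=False)
    modulators: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.deviant_position not in DEVIANT_POSITIONS:
            raise ValueError(f"deviant_position must be in {DEVIANT_POSITIONS}")
        labels = _condition_labels(self.deviant_position)
        object.__setattr__(self, "condition_labels", labels)
        object.__setattr__(
            self, "predictabilities",
            tuple(predictability(p, self.deviant_position)
                  for p in range(1, N_SOUNDS + 1)))
        mods, counts = [], {"std1": 0, "std2": 0}
        for lab in labels:
            if lab in counts:
                counts[lab] += 1
                mods.append(counts[lab])
            else:
                mods.append(0)
        object.__setattr__(self, "modulators", tuple(mods))


@dataclass(frozen=True)
class RunParams:
    """Run-level design parameters.

    The target deviant-to-deviant spacing is Gaussian (mean 5 s, sd 1 s);
    the inter-trial interval realising each target is clipped to
    [1.5, 11.0] s.  Null events are silent gaps inserted at a small rate
    to decorrelate the design from the sampling grid.
    """

    n_blocks: int = 6
    trials_per_block: int = 10
    iti_min: float = 1.5
    iti_max: float = 11.0
    deviant_sep_mean: float = 5.0
    deviant_sep_sd: float = 1.0
    null_rate: float = 0.10
    null_duration: float = TRIAL_DURATION
    lead_in: float = 2.0
    max_consecutive: int = 3       # pseudorandomisation constraint

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class RunSchedule:
    """Ordered trials with absolute onsets for one experimental run."""

    trials: tuple[TrialSequence, ...]
    trial_onsets: np.ndarray           # seconds, strictly increasing
    itis: np.ndarray                   # n_trials − 1 stimulus-free gaps
    null_slots: tuple[int, ...]        # trial indices preceded by a null event
    params: RunParams
    seed: int
    run_index: int

    @property
    def blocks(self) -> list[tuple[int, ...]]:
        k = self.params.trials_per_block
        n = self.params.n_trials
        return [tuple(range(i, i + k)) for i in range(0, n, k)]

    @property
    def duration(self) -> float:
        return float(self.trial_onsets[-1] + TRIAL_DURATION)

    def deviant_positions(self) -> np.ndarray:
        return np.array([t.deviant_position for t in self.trials])


def _deviant_position_sequence(rng: np.random.Generator,
                               params: RunParams) -> np.ndarray:
    """Pseudorandomise deviant positions: 20 of each, short repeat streaks."""
    n_each = params.n_trials // len(DEVIANT_POSITIONS)
    base = np.repeat(DEVIANT_POSITIONS, n_each)
    for _ in range(10_000):
        seq = rng.permutation(base)
        runs = np.diff(np.flatnonzero(
            np.concatenate(([True], seq[1:] != seq[:-1], [True]))))
        if runs.max() <= params.max_consecutive:
            return seq
    raise RuntimeError("could not satisfy pseudorandomisation constraint")


def _pairing_assignment(rng: np.random.Generator, pairings, positions,
                        params: RunParams, run_index: int) -> list:
    """Assign a pairing to every trial, balancing pairing × position cells.

    With 60 trials and 18 cells each cell gets 3 trials plus 6 leftovers;
    the leftovers rotate with the run index so the surplus is spread
    evenly across a session's runs.
    """
    n_pos = len(DEVIANT_POSITIONS)
    per_cell, extra = divmod(params.n_trials // n_pos, len(pairings))
    pools: dict[int, list] = {}
    for i, d in enumerate(DEVIANT_POSITIONS):
        pool = list(pairings) * per_cell
        for j in range(extra):
            pool.append(pairings[(extra * (run_index + i) + j) % len(pairings)])
        rng.shuffle(pool)
        pools[d] = pool
    return [pools[d].pop() for d in positions]


def build_run(params: RunParams | None = None, seed: int = 0, *,
              stimuli: Sequence[Stimulus] | None = None,
              run_index: int = 0) -> RunSchedule:
    """Generate one pseudorandomised run of 60 oddball trials.

    Deviant positions occur exactly ``n_trials/3`` times each.  Each
    inter-trial interval is solved so that the deviant-to-deviant spacing
    targets a draw from N(mean, sd), then clipped to the allowed ITI
    range.  Identical seeds give bit-identical schedules.
    """
    params = params or RunParams()
    if params.deviant_sep_sd <= 0:
        raise ValueError("deviant separation sd must be positive")
    if params.n_trials % len(DEVIANT_POSITIONS):
        raise ValueError("trial count must divide evenly over deviant positions")
    stimuli = list(stimuli) if stimuli is not None else default_pure_tones()
    pairings = build_stimulus_pairings(stimuli)

    rng = np.random.default_rng(seed)
    positions = _deviant_position_sequence(rng, params)
    assigned = _pairing_assignment(rng, pairings, positions, params, run_index)
    trials = tuple(TrialSequence(p, int(d)) for p, d in zip(assigned, positions))

    # ITI solving: target deviant separation minus the tail of the earlier
    # trial (deviant to trial end) and the head of the later one.
    dev_offset = (positions - 1) * SOA
    targets = rng.normal(params.deviant_sep_mean, params.deviant_sep_sd,
                         size=params.n_trials - 1)
    itis = targets - (TRIAL_DURATION - dev_offset[:-1]) - dev_offset[1:]
    itis = np.clip(itis, params.iti_min, params.iti_max)

    null_slots = tuple(np.flatnonzero(
        rng.random(params.n_trials) < params.null_rate).tolist())
    gaps = np.zeros(params.n_trials)
    gaps[list(null_slots)] = params.null_duration

    onsets = np.empty(params.n_trials)
    onsets[0] = params.lead_in + gaps[0]
    for k in range(1, params.n_trials):
        onsets[k] = onsets[k - 1] + TRIAL_DURATION + itis[k - 1] + gaps[k]

    return RunSchedule(trials=trials, trial_onsets=onsets, itis=itis,
                       null_slots=null_slots, params=params, seed=seed,
                       run_index=run_index)


def event_table(run: RunSchedule) -> pd.DataFrame:
    """One row per sound: onset, duration, trial_type, stimulus, modulator.

    Modulators index the repeated standards within each trial (1..count
    separately for std1 and std2); other rows carry NaN.
    """
    rows = []
    for trial_idx, (trial, t0) in enumerate(zip(run.trials, run.trial_onsets)):
        for pos in range(N_SOUNDS):
            lab = trial.condition_labels[pos]
            stim = (trial.pairing.deviant if lab.startswith("dev")
                    else trial.pairing.standard)
            rows.append({
                "onset": t0 + pos * SOA,
                "duration": SOUND_DURATION,
                "trial_type": lab,
                "stimulus": stim.label,
                "trial": trial_idx,
                "predictability": trial.predictabilities[pos],
                "modulator": float(trial.modulators[pos]) or np.nan,
            })
    return pd.DataFrame(rows)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an events table as a BIDS-style TSV ('n/a' for missing)."""
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_run_metadata(run: RunSchedule, stimuli: Sequence[Stimulus],
                       path: str | Path) -> None:
    meta = {
        "seed": run.seed,
        "run_index": run.run_index,
        "params": asdict(run.params),
        "stimuli": [asdict(s) for s in stimuli],
    }
    Path(path).write_text(json.dumps(meta, indent=2))
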