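"""Stimulus timelines for the four oculomotor tasks.

The battery mirrors a tablet-based protocol recorded at a nominal 60 Hz:

* fixation — a stationary dot held 7 s at each of five locations
  (screen center, ±10° horizontal, ±14° vertical);
* pro-saccade — 24 trials over 8 locations × 2 eccentricity classes
  (short: 5° horizontal / 6° vertical; large: 10° horizontal /
  12° vertical), 3 samples per location, pre-target fixation uniform
  1.0–3.5 s, target shown 1.5 s;
* anti-saccade — a 100 ms target at ±10° horizontal, 1200 ms blank,
  400 ms arrow cue at the mirror location, 5 s answer screen;
* smooth pursuit — step–ramp trials (step 1.5°, ramp 8.65 deg/s,
  terminating at 10° eccentricity), one trial per cardinal direction.

Coordinates are degrees of visual angle from screen center, x
right-positive, y up-positive; times are seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

INTER_TRIAL_GAP_S = 0.5

FIXATION_LOCATIONS = [(0.0, 0.0), (-10.0, 0.0), (10.0, 0.0), (0.0, 14.0), (0.0, -14.0)]
FIXATION_DURATION_S = 7.0

PROSACCADE_LOCATIONS = {
    # (x, y) -> eccentricity class
    (-5.0, 0.0): "short", (5.0, 0.0): "short",
    (0.0, -6.0): "short", (0.0, 6.0): "short",
    (-10.0, 0.0): "large", (10.0, 0.0): "large",
    (0.0, -12.0): "large", (0.0, 12.0): "large",
}
PROSACCADE_REPEATS = 3
PROSACCADE_FIX_RANGE_S = (1.0, 3.5)
PROSACCADE_TARGET_S = 1.5

ANTISACCADE_ECC_DEG = 10.0
ANTISACCADE_TARGET_S = 0.100
ANTISACCADE_BLANK_S = 1.200
ANTISACCADE_ARROW_S = 0.400
ANTISACCADE_ANSWER_S = 5.0
ANTISACCADE_FIX_RANGE_S = (1.0, 3.5)
# Trial count is a protocol free parameter (8 per side keeps the task
# under ~3 minutes while giving usable error-rate denominators).
ANTISACCADE_N_TRIALS = 16

PURSUIT_VELOCITY_DPS = 8.65
PURSUIT_STEP_DEG = 1.5
PURSUIT_END_ECC_DEG = 10.0
PURSUIT_FIX_RANGE_S = (1.0, 2.0)
PURSUIT_DIRECTIONS = [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)]


@dataclass(frozen=True)
class FixationTrial:
    t_on: float
    t_off: float
    x: float
    y: float


@dataclass(frozen=True)
class ProsaccadeTrial:
    t_fix_on: float
    t_target_on: float
    t_target_off: float
    target_x: float
    target_y: float
    ecc_class: str  # "short" | "large"

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.target_x, self.target_y))


@dataclass(frozen=True)
class AntisaccadeTrial:
    t_fix_on: float
    t_target_on: float
    side: int  # -1 target left, +1 target right
    t_blank_on: float
    t_arrow_on: float
    t_arrow_off: float
    t_answer_off: float
    arrow_dir: str  # "left" | "right" | "up" | "down"

    @property
    def target_x(self) -> float:
        return self.side * ANTISACCADE_ECC_DEG


@dataclass(frozen=True)
class PursuitTrial:
    t_fix_on: float
    t_ramp_on: float
    t_ramp_off: float
    dir_x: float
    dir_y: float
    step_deg: float = PURSUIT_STEP_DEG
    velocity_dps: float = PURSUIT_VELOCITY_DPS

    def target_position(self, t):
        """Target (x, y) during the ramp; step is opposite the motion."""
        t = np.asarray(t, dtype=float)
        s = np.clip(t - self.t_ramp_on, 0.0, self.t_ramp_off - self.t_ramp_on)
        r = -self.step_deg + self.velocity_dps * s
        return r * self.dir_x, r * self.dir_y


@dataclass(frozen=True)
class TaskSpec:
    task_kind: str  # fixation | prosaccade | antisaccade | pursuit
    trials: tuple = field(default_factory=tuple)
    duration_s: float = 0.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError(f"{self.task_kind}: spec duration must be positive")


def make_fixation_spec(rng: np.random.Generator) -> TaskSpec:
    order = rng.permutation(len(FIXATION_LOCATIONS))
    trials, t = [], 0.0
    for i in order:
        x, y = FIXATION_LOCATIONS[i]
        trials.append(FixationTrial(t_on=t, t_off=t + FIXATION_DURATION_S, x=x, y=y))
        t += FIXATION_DURATION_S + INTER_TRIAL_GAP_S
    return TaskSpec("fixation", tuple(trials), duration_s=t)


def make_prosaccade_spec(rng: np.random.Generator) -> TaskSpec:
    locs = [loc for loc in PROSACCADE_LOCATIONS for _ in range(PROSACCADE_REPEATS)]
    order = rng.permutation(len(locs))
    trials, t = [], 0.0
    for i in order:
        x, y = locs[i]
        fix = rng.uniform(*PROSACCADE_FIX_RANGE_S)
        trials.append(ProsaccadeTrial(
            t_fix_on=t, t_target_on=t + fix, t_target_off=t + fix + PROSACCADE_TARGET_S,
            target_x=x, target_y=y, ecc_class=PROSACCADE_LOCATIONS[(x, y)]))
        t += fix + PROSACCADE_TARGET_S + INTER_TRIAL_GAP_S
    return TaskSpec("prosaccade", tuple(trials), duration_s=t)


def make_antisaccade_spec(rng: np.random.Generator,
                          n_trials: int = ANTISACCADE_N_TRIALS) -> TaskSpec:
    sides = np.repeat([-1, 1], n_trials // 2 + n_trials % 2)[:n_trials]
    rng.shuffle(sides)
    arrows = rng.choice(["left", "right", "up", "down"], size=n_trials)
    trials, t = [], 0.0
    for side, arrow in zip(sides, arrows):
        fix = rng.uniform(*ANTISACCADE_FIX_RANGE_S)
        t_target = t + fix
        t_blank = t_target + ANTISACCADE_TARGET_S
        t_arrow = t_blank + ANTISACCADE_BLANK_S
        t_arrow_off = t_arrow + ANTISACCADE_ARROW_S
        t_end = t_arrow_off + ANTISACCADE_ANSWER_S
        trials.append(AntisaccadeTrial(
            t_fix_on=t, t_target_on=t_target, side=int(side), t_blank_on=t_blank,
            t_arrow_on=t_arrow, t_arrow_off=t_arrow_off, t_answer_off=t_end,
            arrow_dir=str(arrow)))
        t = t_end + INTER_TRIAL_GAP_S
    return TaskSpec("antisaccade", tuple(trials), duration_s=t)


def make_pursuit_spec(rng: np.random.Generator,
                      velocity_dps: float = PURSUIT_VELOCITY_DPS) -> TaskSpec:
    order = rng.permutation(len(PURSUIT_DIRECTIONS))
    ramp_len = (PURSUIT_END_ECC_DEG + PURSUIT_STEP_DEG) / velocity_dps
    trials, t = [], 0.0
    for i in order:
        dx, dy = PURSUIT_DIRECTIONS[i]
        fix = rng.uniform(*PURSUIT_FIX_RANGE_S)
        trials.append(PursuitTrial(
            t_fix_on=t, t_ramp_on=t + fix, t_ramp_off=t + fix + ramp_len,
            dir_x=dx, dir_y=dy, velocity_dps=velocity_dps))
        t += fix + ramp_len + INTER_TRIAL_GAP_S
    return TaskSpec("pursuit", tuple(trials), duration_s=t)


def make_task_battery(seed: int, pursuit_velocity_dps: float = PURSUIT_VELOCITY_DPS,
                      antisaccade_trials: int = ANTISACCADE_N_TRIALS) -> list[TaskSpec]:
    """Full four-task battery with protocol-randomized orders/durations.

    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    return [
        make_fixation_spec(rng),
        make_prosaccade_spec(rng),
        make_antisaccade_spec(rng, n_trials=antisaccade_trials),
        make_pursuit_spec(rng, velocity_dps=pursuit_velocity_dps),
    ]
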