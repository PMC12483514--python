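"""Flexible visual-motion discrimination (FVMD) task trials.

A trial presents two colored saccade targets (red/green, at a left and a
right location, randomly swapped across trials) followed 400 ms later by a
random-dot motion stimulus moving at 135 deg or 315 deg with a given
coherence.  The subject (monkey or network) must saccade to the target whose
color is associated with the motion direction: 315 deg -> red, 135 deg ->
green.  Because target locations are randomized there is no fixed mapping
from motion direction to saccade direction.

Inputs to the network are rate-coded channels: 9 motion units with von Mises
direction tuning and 8 color-target units (2 per hemisphere x color).  Both
carry a transient-plus-sustained temporal profile produced by an exponential
decay filter emulating adaptation in early sensory cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml

RED_DIRECTION = 315.0   # 315 deg motion rewards the red target
GREEN_DIRECTION = 135.0
DIRECTIONS = (135.0, 315.0)

#: target configurations: location of the red target
RED_LEFT, RED_RIGHT = 0, 1
LEFT, RIGHT = 0, 1


@dataclass
class TaskTiming:
    """Trial epoch durations in ms.  All must be integer multiples of dt."""

    dt: float = 20.0
    fixation_dur: float = 100.0
    target_to_motion: float = 400.0
    motion_dur: float = 500.0
    response_grace: float = 100.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("fixation_dur", "target_to_motion", "motion_dur",
                     "response_grace"):
            dur = getattr(self, name)
            if abs(dur / self.dt - round(dur / self.dt)) > 1e-9:
                raise ValueError(f"{name}={dur} is not a multiple of dt={self.dt}")

    @property
    def target_onset(self) -> float:
        return self.fixation_dur

    @property
    def motion_onset(self) -> float:
        return self.fixation_dur + self.target_to_motion

    @property
    def trial_dur(self) -> float:
        return self.fixation_dur + self.target_to_motion + self.motion_dur

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_dur / self.dt))

    @property
    def scoring_onset(self) -> float:
        """Time from which outputs are scored (grace period after motion)."""
        return self.motion_onset + self.response_grace

    def times(self) -> np.ndarray:
        """Stimulus time (ms from trial start) of each input step."""
        return np.arange(self.n_steps) * self.dt


@dataclass
class MotionInputConfig:
    """Parameters of the 9 direction-tuned motion input channels."""

    n_units: int = 9
    kappa: float = 2.0            # von Mises concentration (tuning width)
    sigma_in: float = 0.1         # private (per-channel) noise SD
    tau_mem: float = 100.0        # membrane time constant, ms
    d_amp: float = 2.0            # constant visual-drive amplitude
    noise_sd: float = 2.0         # SD of the shared stimulus noise term
    zero_coh_max_c: float = 1.0   # max(c) in the zero-coherence drive rule
    decay_base: float = 1.0 / 3.0
    decay_unit_ms: float = 100.0  # ms per decay unit; the literal reading is 1.0
    sustained_frac: float = 0.5   # fraction of the drive that does not adapt

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def preferred_dirs(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.n_units, endpoint=False)

    def alpha(self, dt: float) -> float:
        return dt / self.tau_mem


@dataclass
class TargetInputConfig:
    """Parameters of the 8 color-target input channels.

    Channels 0-3 drive the left-hemisphere target module (RF at the RIGHT
    target location), channels 4-7 the right-hemisphere module (RF at the
    LEFT location).  Within each group of four, the first two are the red
    subgroup and the last two the green subgroup.
    """

    n_units: int = 8
    active_amp: float = 4.0 / 3.0
    decay_base: float = 1.0 / 3.0
    decay_unit_ms: float = 100.0
    sustained_frac: float = 0.5   # fraction of the drive that does not adapt


def decay_filter(x, t, base=1.0 / 3.0):
    """Exponential decay filter f(x) = base**t * x.

    ``t`` is elapsed time in decay units (>= 0); the configs above convert
    ms to decay units via ``decay_unit_ms``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("elapsed time must be non-negative")
    return base ** t * x


def adapted_amplitude(x, t, base=1.0 / 3.0, sustained_frac=0.0):
    """Sensory-adaptation profile: transient decay above a sustained floor.

    The decay filter acts on the transient fraction of the drive while a
    fraction ``sustained_frac`` persists, giving the transient-plus-
    sustained response of adapting sensory neurons; inputs remain present
    until the end of the trial.  ``sustained_frac=0`` reproduces the pure
    decay filter.
    """
    return sustained_frac * x + decay_filter((1 - sustained_frac) * x,
                                             t, base)


def motion_input(direction, coherence, timing: TaskTiming,
                 cfg: MotionInputConfig | None = None, rng=None):
    """Time series of the 9 motion input channels for one trial.

    Each unit n follows
    ``r_n = (2/3) (a c exp(kappa cos(th - th_n)) + b N(0, sd) +
    sqrt(2/alpha) N(0, sigma_in)) + d``
    with ``a = 4/exp(kappa)`` after motion onset (0 before), ``b`` a 0/1
    step at motion onset, and ``d`` the decaying constant drive.  For
    zero coherence the tuned term is replaced by the untuned constant
    ``0.4 * max(c)``.  With ``rng=None`` all noise terms are off.

    Returns an array of shape (n_steps, n_units).
    """
    cfg = cfg or MotionInputConfig()
    coherence = float(coherence)
    if not 0.0 <= coherence <= 1.0:
        raise ValueError(f"coherence must lie in [0, 1], got {coherence}")
    times = timing.times()
    n_steps = len(times)
    out = np.zeros((n_steps, cfg.n_units))

    on_target = times >= timing.target_onset
    on_motion = times >= timing.motion_onset

    # tuned visual drive (zero before motion onset)
    if coherence > 0:
        a = 4.0 / np.exp(cfg.kappa)
        dtheta = np.deg2rad(direction - cfg.preferred_dirs)
        tuned = a * coherence * np.exp(cfg.kappa * np.cos(dtheta))
    else:
        tuned = np.full(cfg.n_units, 0.4 * cfg.zero_coh_max_c)
    out[on_motion] += (2.0 / 3.0) * tuned

    if rng is not None:
        alpha = cfg.alpha(timing.dt)
        private = np.sqrt(2.0 / alpha) * rng.normal(
            0.0, cfg.sigma_in, size=(n_steps, cfg.n_units))
        private[~on_target] = 0.0
        shared = rng.normal(0.0, cfg.noise_sd, size=(n_steps, cfg.n_units))
        shared[~on_motion] = 0.0
        out += (2.0 / 3.0) * (private + shared)

    # constant visual drive: on from target onset, adapts from motion onset
    d = np.zeros(n_steps)
    d[on_target] = cfg.d_amp
    t_decay = (times[on_motion] - timing.motion_onset) / cfg.decay_unit_ms
    d[on_motion] = adapted_amplitude(cfg.d_amp, t_decay, cfg.decay_base,
                                     cfg.sustained_frac)
    out += d[:, None]
    return out


def target_input(target_config, timing: TaskTiming,
                 cfg: TargetInputConfig | None = None):
    """Time series of the 8 color-target channels for one trial.

    The subgroup whose color occupies the module's response field is active
    with amplitude 4/3 decaying from target onset; the other subgroup stays
    silent.  Returns shape (n_steps, 8).
    """
    cfg = cfg or TargetInputConfig()
    if target_config not in (RED_LEFT, RED_RIGHT):
        raise ValueError(f"invalid target_config {target_config!r}")
    times = timing.times()
    out = np.zeros((len(times), cfg.n_units))
    on = times >= timing.target_onset
    t_decay = (times[on] - timing.target_onset) / cfg.decay_unit_ms
    amp = adapted_amplitude(cfg.active_amp, t_decay, cfg.decay_base,
                            cfg.sustained_frac)

    # left-hemisphere module sees the right location, and vice versa
    color_at_right = "red" if target_config == RED_RIGHT else "green"
    color_at_left = "green" if target_config == RED_RIGHT else "red"
    idx = np.where(on)[0]
    for module, color in ((0, color_at_right), (1, color_at_left)):
        base = 4 * module
        cols = np.arange(base, base + 2) if color == "red" \
            else np.arange(base + 2, base + 4)
        out[np.ix_(idx, cols)] = amp[:, None]
    return out


def correct_side(direction, target_config):
    """Response side (LEFT/RIGHT) rewarded for a direction/config pair."""
    rewarded_color = "red" if direction == RED_DIRECTION else "green"
    red_loc = RIGHT if target_config == RED_RIGHT else LEFT
    return red_loc if rewarded_color == "red" else 1 - red_loc


@dataclass
class TrialBatch:
    """A batch of FVMD trials: input tensors plus per-trial labels."""

    motion_input: np.ndarray      # (steps, trials, 9)
    target_input: np.ndarray      # (steps, trials, 8)
    direction: np.ndarray         # degrees, {135, 315}
    coherence: np.ndarray         # fraction in [0, 1]
    target_config: np.ndarray     # RED_LEFT / RED_RIGHT
    correct_output: np.ndarray    # response unit index (LEFT/RIGHT)
    timing: TaskTiming

    @property
    def n_trials(self) -> int:
        return self.motion_input.shape[1]

    @property
    def inputs(self) -> np.ndarray:
        """Concatenated (steps, trials, 17) input tensor."""
        return np.concatenate([self.motion_input, self.target_input], axis=2)

    @property
    def times(self) -> np.ndarray:
        return self.timing.times()

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("motion_input", data=self.motion_input)
            f.create_dataset("target_input", data=self.target_input)
            lab = f.create_group("labels")
            lab.create_dataset("direction", data=self.direction)
            lab.create_dataset("coherence", data=self.coherence)
            lab.create_dataset("target_config", data=self.target_config)
            lab.create_dataset("correct_output", data=self.correct_output)
            for k, v in asdict(self.timing).items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            timing = TaskTiming(**{k: float(f.attrs[k]) for k in
                                   ("dt", "fixation_dur", "target_to_motion",
                                    "motion_dur", "response_grace")})
            return cls(
                motion_input=f["motion_input"][...],
                target_input=f["target_input"][...],
                direction=f["labels/direction"][...],
                coherence=f["labels/coherence"][...],
                target_config=f["labels/target_config"][...],
                correct_output=f["labels/correct_output"][...],
                timing=timing,
            )


def generate_batch(n_trials, coherences, timing: TaskTiming | None = None,
                   rng=None, motion_cfg: MotionInputConfig | None = None,
                   target_cfg: TargetInputConfig | None = None,
                   noise: bool = True) -> TrialBatch:
    """Generate a balanced batch of FVMD trials.

    Directions, target configurations and coherences are balanced across
    trials up to rounding, then shuffled.  For zero-coherence trials the
    rewarded side is drawn at random with probability 0.5.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    coherences = list(coherences)
    if not coherences:
        raise ValueError("need at least one coherence level")
    timing = timing or TaskTiming()
    motion_cfg = motion_cfg or MotionInputConfig()
    target_cfg = target_cfg or TargetInputConfig()
    rng = rng if rng is not None else np.random.default_rng()

    cells = [(d, c, tc) for c in coherences for d in DIRECTIONS
             for tc in (RED_LEFT, RED_RIGHT)]
    reps = int(np.ceil(n_trials / len(cells)))
    rows = (cells * reps)[:n_trials]
    order = rng.permutation(n_trials)
    direction = np.array([rows[i][0] for i in order])
    coherence = np.array([rows[i][1] for i in order])
    tconf = np.array([rows[i][2] for i in order])

    correct = np.array([correct_side(d, tc) for d, tc in zip(direction, tconf)])
    zero = coherence == 0
    correct[zero] = rng.integers(0, 2, size=zero.sum())

    n_steps = timing.n_steps
    mo = np.empty((n_steps, n_trials, motion_cfg.n_units))
    ta = np.empty((n_steps, n_trials, target_cfg.n_units))
    noise_rng = rng if noise else None
    for i in range(n_trials):
        mo[:, i] = motion_input(direction[i], coherence[i], timing,
                                motion_cfg, noise_rng)
        ta[:, i] = target_input(tconf[i], timing, target_cfg)
    return TrialBatch(mo, ta, direction, coherence, tconf, correct, timing)


def load_config(path):
    """Load task configs from a YAML file with optional sections
    ``timing``, ``motion``, ``target``."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return (TaskTiming(**raw.get("timing", {})),
            MotionInputConfig(**raw.get("motion", {})),
            TargetInputConfig(**raw.get("target", {})))
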