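"""Synthetic-cohort generator for the mouse-tracking classification
task.

Each simulated agent carries a latent unhealthy = tasty trait
``u ~ N(0, 1)``.  The trait drives four observable channels:

choice
    P(classify tasty) = logistic(a0 + a1*[unhealthy] -
    a2*max(u*, 0)*[healthy]), so stronger-trait agents reject healthy
    items as tasty while unhealthy items are unaffected.
conflict -> motor behaviour
    A per-trial conflict level c = softplus(k0 +
    k1*max(u*, 0)*[healthy, tasty] + k2*[not tasty]) feeds an
    attractor-style trajectory model: the
    cursor heads for the chosen box while a lateral pull toward the
    competing box (proportional to c, decaying over the first half of
    the movement) bends the path, and c also lengthens movement time.
    Conflict therefore loads on healthy-items-affirmed-as-tasty trials,
    where the trait bites.
explicit scale
    Three Likert items = clip(round(4 + lambda*u + noise), 1, 7).
diet quality
    FFQ responses are constructed so the diet quality score tracks
    clip(10 - delta*u + noise, 5, 15) under the default scoring config.

A goal manipulation ("hedonic" condition) shifts the *effective* trait
u* = u + shift — a state activation on top of the stable trait, leaving
the explicit items (driven by u) nearly unchanged.

Everything is deterministic under the config seed; per-agent substreams
are spawned from one seed sequence.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .indices import DQSConfig, default_dqs_config

GENDERS = ("female", "male", "other")
GENDER_P = (0.60, 0.38, 0.02)
EDUCATIONS = ("primary", "secondary", "bachelor", "master")
EDUCATION_P = (0.05, 0.45, 0.35, 0.15)


@dataclass
class SimulationConfig:
    """All generative parameters; defaults follow the task design of
    the validation studies (10 + 10 stimuli shown twice, 100-Hz
    tracking on a 1920x1080 screen) with effect sizes chosen to yield
    explicit-implicit validity correlations around .3."""

    n_participants: int = 200
    condition: str = "none"           # "none", "utilitarian", "hedonic"

    # task design
    n_healthy_stimuli: int = 10
    n_unhealthy_stimuli: int = 10
    repetitions: int = 2

    # geometry (px); screen y grows downward
    screen: tuple[int, int] = (1920, 1080)
    start: tuple[float, float] = (960.0, 980.0)
    left_box: tuple[float, float] = (160.0, 80.0)
    right_box: tuple[float, float] = (1760.0, 80.0)
    sampling_interval_ms: float = 10.0

    # latent conflict model
    conflict_intercept: float = 0.5           # k0
    conflict_uti_slope: float = 1.0           # k1, healthy x tasty trials
    conflict_not_tasty: float = 1.5           # k2
    condition_shift: float = 0.5              # added to u* under "hedonic"

    # choice model (logits)
    choice_intercept: float = 1.4             # a0
    choice_unhealthy_bonus: float = 0.2       # a1
    choice_healthy_uti_penalty: float = 1.0   # a2

    # explicit scale
    scale_loading: float = 1.2
    scale_item_sd: float = 0.8

    # diet quality
    dqs_slope: float = 1.0
    dqs_sd: float = 2.5

    # motor model
    base_duration_ms: float = 900.0
    duration_per_conflict_ms: float = 350.0
    duration_lognorm_sd: float = 0.25         # trial-level multiplicative
    agent_speed_sd: float = 0.10              # agent-level multiplicative
    stimulus_rt_sd_ms: float = 20.0           # stimulus-level additive
    lateral_pull_px: float = 95.0            # total lateral impulse per c
    position_noise_px: float = 16.0           # per-step Gaussian jitter
    click_jitter_px: float = 10.0
    start_jitter_px: float = 5.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if min(self.n_healthy_stimuli, self.n_unhealthy_stimuli,
               self.repetitions) < 1:
            raise ConfigError("stimulus counts and repetitions must be "
                              "positive")
        if self.sampling_interval_ms <= 0:
            raise ConfigError("sampling interval must be positive")
        if self.condition not in ("none", "utilitarian", "hedonic"):
            raise ConfigError(f"unknown condition {self.condition!r}")

    @property
    def trials_per_participant(self) -> int:
        return (self.n_healthy_stimuli + self.n_unhealthy_stimuli) \
            * self.repetitions

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("screen", "start", "left_box", "right_box"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _softplus(x: float) -> float:
    return math.log1p(math.exp(-abs(x))) + max(x, 0.0)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_trajectory(start, target, competing, conflict: float,
                        duration_ms: float, config: SimulationConfig,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One trial's cursor samples at the configured sampling interval.

    The cursor steps toward the chosen target so as to arrive when the
    movement time elapses; a lateral pull toward the competing box
    (total impulse ``lateral_pull_px * conflict`` px, decaying linearly
    over the first half of the movement) and per-step Gaussian jitter
    bend the path.  The final sample is the click pixel itself.
    """
    if conflict < 0:
        raise ConfigError("conflict must be non-negative")
    dt = config.sampling_interval_ms
    n = max(2, int(round(duration_ms / dt)))
    if n > 100000:
        raise ConfigError("pathological config: trajectory exceeds step cap")
    sx, sy = float(start[0]), float(start[1])
    tx, ty = float(target[0]), float(target[1])
    cx, cy = float(competing[0]), float(competing[1])
    pdx, pdy = cx - sx, cy - sy
    pnorm = math.hypot(pdx, pdy)
    pdx, pdy = (pdx / pnorm, pdy / pnorm) if pnorm else (0.0, 0.0)
    # per-step pull so the decaying profile integrates to pull*conflict
    gain = config.lateral_pull_px * conflict * 4.0 / n
    noise = (rng.normal(0.0, config.position_noise_px, size=(n, 2))
             if config.position_noise_px > 0 else np.zeros((n, 2)))
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0], ys[0] = sx, sy
    px, py = sx, sy
    for i in range(1, n + 1):
        remaining = n - i + 1
        step_x = (tx - px) / remaining
        step_y = (ty - py) / remaining
        decay = max(0.0, 1.0 - 2.0 * (i - 1) / n)
        pm = gain * decay
        px += step_x + pdx * pm + noise[i - 1, 0]
        py += step_y + pdy * pm + noise[i - 1, 1]
        xs[i], ys[i] = px, py
    xs[n], ys[n] = tx, ty          # last sample is the click pixel
    t_ms = np.arange(n + 1, dtype=float) * dt
    return t_ms, np.column_stack([xs, ys])


def _ffq_for_target(target_dqs: int, dqs_config: DQSConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Invert the default component scoring: pick item responses whose
    component scores sum to ``target_dqs``.  A generator convenience —
    real questionnaires are not constructed this way."""
    n_comp = len(dqs_config.components)
    extras = np.zeros(n_comp, dtype=int)
    budget = target_dqs - n_comp
    order = rng.permutation(n_comp)
    while budget > 0:
        for idx in order:
            if budget > 0 and extras[idx] < 2:
                extras[idx] += 1
                budget -= 1
    # representative item values per (direction, component score)
    rep = {("healthy", 1): 2, ("healthy", 2): 4, ("healthy", 3): 6,
           ("unhealthy", 1): 6, ("unhealthy", 2): 3, ("unhealthy", 3): 2}
    ffq = np.zeros(dqs_config.n_items, dtype=int)
    for comp, extra in zip(dqs_config.components, extras):
        value = rep[(comp.direction, 1 + extra)]
        vals = np.full(len(comp.items), value)
        if len(vals) >= 2:           # mean-preserving jitter
            i, j = rng.choice(len(vals), size=2, replace=False)
            vals[i] += 1
            vals[j] -= 1
        ffq[np.array(comp.items) - 1] = vals
    return ffq


def simulate_cohort(config: SimulationConfig | None = None,
                    dqs_config: DQSConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               pd.DataFrame]:
    """Generate one cohort: (participants, trials, samples, truth).

    The first three tables use the public interchange schema; ``truth``
    holds the latent trait and effective trait per agent and never
    feeds back into them.
    """
    config = config or SimulationConfig()
    config.validate()
    dqs_config = dqs_config or default_dqs_config()

    stimuli = ([(f"h{i+1:02d}", "healthy")
                for i in range(config.n_healthy_stimuli)]
               + [(f"u{i+1:02d}", "unhealthy")
                  for i in range(config.n_unhealthy_stimuli)])

    root = np.random.SeedSequence(config.seed)
    stim_rng = np.random.default_rng(root.spawn(1)[0])
    stim_rt_offset = {
        sid: stim_rng.normal(0.0, config.stimulus_rt_sd_ms)
        for sid, _ in stimuli}
    agent_seeds = root.spawn(config.n_participants + 1)[1:]

    p_rows, t_rows, truth_rows = [], [], []
    s_pid, s_tid, s_t, s_x, s_y = [], [], [], [], []
    cfg = config
    for a, seq in enumerate(agent_seeds):
        rng = np.random.default_rng(seq)
        pid = f"p{a+1:04d}"
        u = float(rng.normal())
        u_eff = u + (cfg.condition_shift if cfg.condition == "hedonic"
                     else 0.0)
        age = int(np.clip(round(rng.normal(41, 14)), 18, 80))
        gender = rng.choice(GENDERS, p=GENDER_P)
        education = rng.choice(EDUCATIONS, p=EDUCATION_P)
        items = np.clip(np.round(
            4.0 + cfg.scale_loading * u + rng.normal(0, cfg.scale_item_sd, 3)
        ), 1, 7).astype(int)
        target_dqs = int(np.clip(round(
            10.0 - cfg.dqs_slope * u + rng.normal(0, cfg.dqs_sd)), 5, 15))
        ffq = _ffq_for_target(target_dqs, dqs_config, rng)
        agent_speed = math.exp(rng.normal(0.0, cfg.agent_speed_sd))

        order = rng.permutation(
            np.repeat(np.arange(len(stimuli)), cfg.repetitions))
        for k, stim_idx in enumerate(order):
            sid, ftype = stimuli[stim_idx]
            tid = f"t{k+1:03d}"
            healthy = ftype == "healthy"
            logit = (cfg.choice_intercept
                     + cfg.choice_unhealthy_bonus * (not healthy)
                     - cfg.choice_healthy_uti_penalty * max(u_eff, 0.0)
                     * healthy)
            tasty = rng.random() < _logistic(logit)
            conflict = _softplus(
                cfg.conflict_intercept
                + cfg.conflict_uti_slope * max(u_eff, 0.0) * healthy * tasty
                + cfg.conflict_not_tasty * (not tasty))
            side = "left" if tasty else "right"
            box = cfg.left_box if tasty else cfg.right_box
            competing = cfg.right_box if tasty else cfg.left_box
            start = (cfg.start[0] + rng.normal(0, cfg.start_jitter_px),
                     cfg.start[1] + rng.normal(0, cfg.start_jitter_px))
            click = (box[0] + rng.normal(0, cfg.click_jitter_px),
                     box[1] + rng.normal(0, cfg.click_jitter_px))
            duration = ((cfg.base_duration_ms
                         + cfg.duration_per_conflict_ms * conflict
                         + stim_rt_offset[sid])
                        * agent_speed
                        * math.exp(rng.normal(0.0, cfg.duration_lognorm_sd)))
            t_ms, xy = simulate_trajectory(
                start, click, competing, conflict, duration, cfg, rng)
            m = len(t_ms)
            s_pid.extend([pid] * m)
            s_tid.extend([tid] * m)
            s_t.append(t_ms)
            s_x.append(xy[:, 0])
            s_y.append(xy[:, 1])
            t_rows.append((pid, tid, sid, ftype,
                           "tasty" if tasty else "not_tasty", side, k + 1,
                           xy[0, 0], xy[0, 1], xy[-1, 0], xy[-1, 1]))
        p_rows.append((pid, age, gender, education, cfg.condition,
                       *items, *ffq))
        truth_rows.append((pid, u, u_eff, cfg.condition))

    participants = pd.DataFrame(p_rows, columns=[
        "participant_id", "age", "gender", "education", "condition",
        "uti_item_1", "uti_item_2", "uti_item_3",
        *[f"ffq_{i+1}" for i in range(dqs_config.n_items)]])
    trials = pd.DataFrame(t_rows, columns=[
        "participant_id", "trial_id", "stimulus_id", "food_type",
        "classification", "response_side", "presentation_index",
        "start_x_px", "start_y_px", "click_x_px", "click_y_px"])
    samples = pd.DataFrame({
        "participant_id": s_pid, "trial_id": s_tid,
        "t_ms": np.concatenate(s_t), "x_px": np.concatenate(s_x),
        "y_px": np.concatenate(s_y)})
    truth = pd.DataFrame(truth_rows, columns=[
        "participant_id", "u", "u_effective", "condition"])
    return participants, trials, samples, truth


def simulate_condition_experiment(config: SimulationConfig | None = None,
                                  n_per_arm: int = 100,
                                  ) -> tuple[pd.DataFrame, pd.DataFrame,
                                             pd.DataFrame, pd.DataFrame]:
    """Two-arm goal-manipulation cohort: utilitarian vs hedonic, each
    arm generated from a derived sub-seed, merged into one dataset."""
    config = config or SimulationConfig()
    out = []
    for arm_idx, condition in enumerate(("utilitarian", "hedonic")):
        arm_cfg = replace(config, n_participants=n_per_arm,
                          condition=condition,
                          seed=(config.seed * 2 + arm_idx) % (2 ** 31))
        p, t, s, tr = simulate_cohort(arm_cfg)
        prefix = "u" if condition == "utilitarian" else "h"
        for df in (p, t, s, tr):
            df["participant_id"] = prefix + df["participant_id"]
        out.append((p, t, s, tr))
    return tuple(pd.concat([o[i] for o in out], ignore_index=True)
                 for i in range(4))
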