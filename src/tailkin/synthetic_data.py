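"""Synthetic landmark-trajectory generator for detection-dog search studies.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without the study's videos: eight-ish dogs with
individual wag styles (random effects on bias, amplitudes, frequency),
oscillatory tail wagging with separate left/right half-cycle amplitudes, a
class-conditional kinematic shift in the target area whose size scales with
odour concentration, overhead 60 fps landmark streams with detector jitter,
dropout and confidence scores, and trial structure with rotating target
placement, alert events, and threshold (dilution-series) sessions.

The generating tail angle is

    theta(t) = bias + A(t) * sin(2*pi*f*t + phi) + eps,

with A(t) alternating between ``amp_right`` on positive half-cycles and
``amp_left`` on negative ones (wag reach measured separately per side), and
eps white jitter.  Landmarks are placed by inverting the body-frame
geometry of :mod:`tailkin.kinematics`, so with noise zeroed the extracted
angle reproduces the generating one to float precision — the
generator/extractor inverse pair is the package's core correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import tracking_io
from .tracking_io import AREA_BEHAVIOURS, EventRecord, TrajectorySegment, TrialLayout

DEG = np.pi / 180.0

# dilution series of the threshold test: training concentration 10^-3 then
# one log unit lower per step, with the class-effect multiplier halving
# (and collapsing toward chance at the last step)
TEST2_EFFECT_STEPS = (1.0, 0.5, 0.25, 0.1)
TEST2_DILUTION_EXPONENTS = (-3, -4, -5, -6)
TEST1_DILUTION_EXPONENT = -2


@dataclass(frozen=True)
class WagParams:
    """Parameters of one dog's wag waveform in one condition (degrees, Hz)."""

    bias: float = 0.0          # mean tail offset, + = dog's right
    amp_right: float = 28.0    # oscillation reach to the right
    amp_left: float = 28.0     # oscillation reach to the left
    freq: float = 3.0          # wag frequency
    phase: float = 0.0         # radians
    noise_sd: float = 2.0      # white jitter on theta

    def __post_init__(self):
        if min(self.amp_right, self.amp_left, self.freq, self.noise_sd) < 0:
            raise ValueError("amp_right, amp_left, freq and noise_sd must be >= 0")
        if abs(self.bias) >= 90:
            raise ValueError("|bias| must be < 90 deg")

    def shifted(self, delta: "WagShift", scale: float = 1.0) -> "WagParams":
        """Apply an additive shift (clipped back into the invariants)."""
        return WagParams(
            bias=float(np.clip(self.bias + scale * delta.bias, -89.0, 89.0)),
            amp_right=max(0.0, self.amp_right + scale * delta.amp_right),
            amp_left=max(0.0, self.amp_left + scale * delta.amp_left),
            freq=max(0.05, self.freq + scale * delta.freq),
            phase=self.phase + scale * delta.phase,
            noise_sd=max(0.0, self.noise_sd + scale * delta.noise_sd),
        )


@dataclass(frozen=True)
class WagShift:
    """Additive delta on WagParams (the target-area effect)."""

    bias: float = 0.0
    amp_right: float = 0.0
    amp_left: float = 0.0
    freq: float = 0.0
    phase: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class DogProfile:
    dog_id: str
    baseline: WagParams
    target_shift: WagShift
    body_scale: float = 110.0   # shoulders→tail-base distance, px
    tail_scale: float = 65.0    # tail-base→tail-tip distance, px

    def __post_init__(self):
        if self.body_scale <= 0 or self.tail_scale <= 0:
            raise ValueError("body_scale and tail_scale must be > 0")

    def params_for(self, sub_label: str, effect_scale: float) -> WagParams:
        if sub_label == "target":
            return self.baseline.shifted(self.target_shift, effect_scale)
        return self.baseline


@dataclass(frozen=True)
class StudyDesign:
    n_dogs: int = 8
    sessions: int = 10
    trials_per_session: int = 10
    fps: float = 60.0
    duration_mean: float = 3.34   # seconds, per-segment search duration
    duration_sd: float = 3.45
    duration_min: float = 1.0     # truncation floor
    effect_scale: float = 1.0     # multiplier on target_shift (odour concentration)
    seed: int = 0
    # probability the dog alerts in the target area at full effect; decays
    # toward 0.5 as the effect (concentration) shrinks
    alert_prob_full: float = 0.98
    false_alert_prob: float = 0.01
    heading_sd: float = 0.4       # rad/sqrt(s), OU drive on heading
    heading_kappa: float = 1.0    # OU mean reversion, 1/s
    speed_px_s: float = 15.0      # body drift speed scale
    tip_lag: float = 0.03         # s: tip angle = middle angle + lag * dtheta/dt
    waveform: str = "sine"        # {sine, square, triangle}

    def __post_init__(self):
        if self.fps <= 0 or self.duration_mean <= 0 or self.duration_sd <= 0:
            raise ValueError("fps and duration moments must be > 0")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")

    def alert_prob(self, effect_scale: float) -> float:
        return 0.5 + (self.alert_prob_full - 0.5) * min(1.0, effect_scale)


@dataclass(frozen=True)
class NoiseModel:
    jitter_sd: float = 1.5               # px isotropic landmark noise
    dropout_rate: float = 0.02           # per-frame degraded-detection probability
    conf_high: tuple[float, float] = (0.92, 0.04)
    conf_low: tuple[float, float] = (0.30, 0.10)

    def __post_init__(self):
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(jitter_sd=0.0, dropout_rate=0.0, conf_high=(1.0, 0.0), conf_low=(1.0, 0.0))


@dataclass(frozen=True)
class PopulationSpec:
    """Mean and spread of every dog-profile field (degrees, Hz, px).

    Defaults are the study conditions the generator emulates: moderate
    individual variation around a symmetric ~28 deg, ~3 Hz wag, and a
    population-level target effect that increases *left* amplitude (with a
    small leftward bias shift) — the group-level lateralisation signature
    the analysis is designed to detect.  Phase is uniform on [0, 2*pi).
    """

    bias: tuple[float, float] = (0.0, 8.0)
    amp_right: tuple[float, float] = (28.0, 6.0)
    amp_left: tuple[float, float] = (28.0, 6.0)
    freq: tuple[float, float] = (3.0, 0.6)
    noise_sd: tuple[float, float] = (2.0, 0.5)
    shift_bias: tuple[float, float] = (-5.0, 2.0)
    shift_amp_right: tuple[float, float] = (0.0, 2.0)
    shift_amp_left: tuple[float, float] = (18.0, 4.0)
    shift_freq: tuple[float, float] = (0.0, 0.2)
    body_scale: tuple[float, float] = (110.0, 12.0)
    tail_scale: tuple[float, float] = (65.0, 8.0)

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            _, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: spread must be >= 0")

    @classmethod
    def strong_lateralization(cls) -> "PopulationSpec":
        """A recovery-oracle construction: the shared left-amplitude target
        effect (+35 deg) dominates every source of individual variation,
        and the lateral-bias channel is quiet — so a classifier that
        generalises across dogs at all must reach high accuracy, and a
        failure indicts the pipeline rather than between-dog overlap."""
        return cls(
            bias=(0.0, 3.0), amp_left=(25.0, 3.0), amp_right=(25.0, 3.0),
            freq=(3.0, 0.5), noise_sd=(2.0, 0.3),
            shift_amp_left=(35.0, 2.0), shift_bias=(0.0, 0.5),
            shift_amp_right=(0.0, 1.0), shift_freq=(0.0, 0.1),
        )


# ---------------------------------------------------------------------------
# dog profiles
# ---------------------------------------------------------------------------

def sample_dog_profiles(
    n_dogs: int,
    population: PopulationSpec | None = None,
    seed: int = 0,
) -> list[DogProfile]:
    """Draw dog profiles (random effects) from the population spec.

    Gaussian draws per field, clipped only where an invariant demands it
    (amplitudes, scales >= 0; |bias| < 90).  Deterministic given seed.
    """
    if n_dogs < 1:
        raise ValueError("n_dogs must be >= 1")
    pop = population or PopulationSpec()
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_dogs):
        g = lambda m_s: float(rng.normal(*m_s))
        baseline = WagParams(
            bias=float(np.clip(g(pop.bias), -89.0, 89.0)),
            amp_right=max(0.0, g(pop.amp_right)),
            amp_left=max(0.0, g(pop.amp_left)),
            freq=max(0.05, g(pop.freq)),
            phase=float(rng.uniform(0.0, 2 * np.pi)),
            noise_sd=max(0.0, g(pop.noise_sd)),
        )
        shift = WagShift(
            bias=g(pop.shift_bias),
            amp_right=g(pop.shift_amp_right),
            amp_left=g(pop.shift_amp_left),
            freq=g(pop.shift_freq),
        )
        profiles.append(
            DogProfile(
                dog_id=f"dog{i:02d}",
                baseline=baseline,
                target_shift=shift,
                body_scale=max(10.0, g(pop.body_scale)),
                tail_scale=max(5.0, g(pop.tail_scale)),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# durations
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _truncated_lognormal_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal whose truncation below ``lower`` has the
    requested mean and SD.  Solved numerically from the analytic truncated
    moments; a plain log-normal matched to the moments *before* truncation
    would overshoot the mean once the floor is applied."""

    def trunc_moments(mu, sigma):
        a = (np.log(lower) - mu) / sigma
        tail = stats.norm.sf(a)
        m1 = np.exp(mu + 0.5 * sigma**2) * stats.norm.sf(a - sigma) / tail
        m2 = np.exp(2 * mu + 2 * sigma**2) * stats.norm.sf(a - 2 * sigma) / tail
        return m1, np.sqrt(max(m2 - m1**2, 1e-12))

    def eqs(x):
        m, s = trunc_moments(x[0], x[1])
        return [m - mean, s - sd]

    mu0 = np.log(mean) - 0.5 * np.log(1 + (sd / mean) ** 2)
    s0 = np.sqrt(np.log(1 + (sd / mean) ** 2))
    sol = optimize.fsolve(eqs, [mu0, s0], full_output=False)
    return float(sol[0]), float(sol[1])


def sample_durations(n: int, design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Per-segment search durations: truncated log-normal matching the
    design's mean/SD (defaults 3.34 s / 3.45 s, floor 1.0 s)."""
    mu, sigma = _truncated_lognormal_params(design.duration_mean, design.duration_sd, design.duration_min)
    a = (np.log(design.duration_min) - mu) / sigma
    u = rng.uniform(stats.norm.cdf(a), 1.0, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


# ---------------------------------------------------------------------------
# segment simulation
# ---------------------------------------------------------------------------

def _waveform(phase_arg: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sine":
        return np.sin(phase_arg)
    if kind == "square":
        return np.sign(np.sin(phase_arg))
    if kind == "triangle":
        return 2.0 / np.pi * np.arcsin(np.sin(phase_arg))
    raise ValueError(f"unknown waveform {kind!r}")


def generate_theta(
    params: WagParams,
    t: np.ndarray,
    rng: np.random.Generator,
    waveform: str = "sine",
) -> np.ndarray:
    """The generating tail angle: asymmetric oscillation around the bias."""
    s = _waveform(2 * np.pi * params.freq * t + params.phase, waveform)
    amp = np.where(s >= 0, params.amp_right, params.amp_left)
    eps = rng.normal(0.0, params.noise_sd, size=t.size) if params.noise_sd > 0 else 0.0
    return params.bias + amp * s + eps


def simulate_segment(
    profile: DogProfile,
    area: str,
    duration: float,
    design: StudyDesign,
    noise: NoiseModel,
    seed,
    sub_label: str = "no_odour",
    t_offset: float = 0.0,
    effect_scale: float | None = None,
    return_theta: bool = False,
) -> pd.DataFrame:
    """Simulate the landmark stream for one area visit.

    Frames at 1/fps spacing over [t_offset, t_offset + duration).  The dog's
    heading follows an Ornstein–Uhlenbeck random walk and its tail-base
    position a smooth drift, so the body frame is exercised under rotation;
    landmarks are placed by inverting the kinematics body-frame geometry;
    detector noise (jitter, dropout, confidence) is applied last.
    Returns a landmark table (columns ``kinematics.FRAME_COLUMNS``).
    """
    if area not in AREA_BEHAVIOURS:
        raise ValueError(f"invalid area label {area!r}")
    if duration < 2.0 / design.fps:
        raise ValueError(f"duration {duration} too short for 2 frames at {design.fps} fps")
    rng = np.random.default_rng(seed)
    es = design.effect_scale if effect_scale is None else effect_scale
    params = profile.params_for(sub_label, es)

    n = int(np.floor(duration * design.fps))
    rel_t = np.arange(n) / design.fps
    t = t_offset + rel_t
    theta = generate_theta(params, rel_t, rng, design.waveform)

    # heading: OU around an initial direction; position: smooth drift
    dt = 1.0 / design.fps
    psi = np.empty(n)
    psi[0] = rng.uniform(0, 2 * np.pi)
    drive = rng.normal(0.0, design.heading_sd * np.sqrt(dt), size=n - 1)
    for i in range(1, n):
        psi[i] = psi[i - 1] - design.heading_kappa * (psi[i - 1] - psi[0]) * dt + drive[i - 1]
    step = rng.normal(0.0, design.speed_px_s * np.sqrt(dt), size=(n, 2))
    base = np.array([640.0, 360.0]) + np.cumsum(step, axis=0)

    # body axis b: unit shoulders→tail-base; right axis r = (-b_y, b_x)
    b = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    r = np.stack([-b[:, 1], b[:, 0]], axis=1)
    B = base
    S = B - profile.body_scale * b
    th = theta * DEG
    dir_mid = b * np.cos(th)[:, None] + r * np.sin(th)[:, None]
    M = B + 0.5 * profile.tail_scale * dir_mid
    # tip lags/leads via the angle's rate of change ("excessive mobility")
    dth = np.gradient(theta, rel_t) if n > 1 else np.zeros(n)
    th_tip = (theta + design.tip_lag * dth) * DEG
    dir_tip = b * np.cos(th_tip)[:, None] + r * np.sin(th_tip)[:, None]
    T = B + profile.tail_scale * dir_tip
    nose = S - 0.45 * profile.body_scale * b
    head = S - 0.25 * profile.body_scale * b

    pos = {"nose": nose, "front_head": head, "shoulders": S, "tail_base": B, "tail_middle": M, "tail_tip": T}
    if noise.jitter_sd > 0:
        for k in pos:
            pos[k] = pos[k] + rng.normal(0.0, noise.jitter_sd, size=(n, 2))
    conf = np.clip(rng.normal(*noise.conf_high, size=n), 0.0, 1.0)
    if noise.dropout_rate > 0:
        drop = rng.random(n) < noise.dropout_rate
        conf[drop] = np.clip(rng.normal(*noise.conf_low, size=int(drop.sum())), 0.0, 1.0)
        pos["tail_middle"][drop] = np.nan
        pos["tail_tip"][drop] = np.nan

    data = {"t": t}
    for k in ("nose", "front_head", "shoulders", "tail_base", "tail_middle", "tail_tip"):
        data[f"{k}_x"] = pos[k][:, 0]
        data[f"{k}_y"] = pos[k][:, 1]
    data["conf"] = conf
    frames_df = pd.DataFrame(data)
    if return_theta:
        return frames_df, theta
    return frames_df


# ---------------------------------------------------------------------------
# trials and studies
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """Everything needed to write one trial to disk and re-segment it."""

    dog_id: str
    session: int
    trial: int
    test_phase: str
    dilution_exponent: int
    layout: TrialLayout
    frames: pd.DataFrame            # full trial landmark stream (incl. alert span)
    events: list[EventRecord]


@dataclass
class StudyDataset:
    segments: list[TrajectorySegment]
    metadata: pd.DataFrame
    trials: list[TrialRecord]
    profiles: list[DogProfile]
    design: StudyDesign


def _trial_seed(base: int, *idx: int):
    return [int(base) & 0x7FFFFFFF, *map(int, idx)]


def simulate_trial(
    profile: DogProfile,
    dog_idx: int,
    session: int,
    trial: int,
    design: StudyDesign,
    noise: NoiseModel,
    layout: TrialLayout,
    effect_scale: float,
    test_phase: str,
    dilution_exponent: int,
) -> tuple[TrialRecord, list[TrajectorySegment]]:
    """One trial: the dog visits all three areas in random order; the target
    visit of a hit trial gains a 1 s pre-alert buffer plus an alert span,
    both excluded from the returned search segment (mirroring the excision
    rule, so re-segmenting the written trial reproduces the segment)."""
    rng = np.random.default_rng(_trial_seed(design.seed, dog_idx, session, trial))
    order = list(rng.permutation(list(AREA_BEHAVIOURS)))
    durations = sample_durations(len(order), design, rng)
    alerted = layout.outcome == "hit"

    frames_parts, events, segments = [], [], []
    t_cursor = 0.0
    for area, dur in zip(order, durations):
        sub = layout.mapping[area]
        search_dur = float(dur)
        visit_dur = search_dur
        has_alert = alerted and sub == "target"
        if has_alert:
            alert_dur = float(rng.uniform(4.0, 6.0))
            visit_dur = search_dur + tracking_io.PRE_ALERT_BUFFER_S + alert_dur
        seg_seed = _trial_seed(design.seed, dog_idx, session, trial, AREA_BEHAVIOURS.index(area))
        frames = simulate_segment(
            profile, area, visit_dur, design, noise, seg_seed,
            sub_label=sub, t_offset=t_cursor, effect_scale=effect_scale,
        )
        frames_parts.append(frames)
        events.append(EventRecord(area, t_cursor, t_cursor + visit_dur))
        if has_alert:
            a_start = t_cursor + search_dur + tracking_io.PRE_ALERT_BUFFER_S
            events.append(EventRecord("alert", a_start, t_cursor + visit_dur))
        # the search segment excludes the pre-alert buffer and alert span
        tvals = frames["t"].to_numpy()
        keep = tvals < t_cursor + search_dur
        seg_frames = frames.loc[keep].reset_index(drop=True)
        if len(seg_frames) >= 2:
            segments.append(
                TrajectorySegment(
                    frames=seg_frames,
                    dog_id=profile.dog_id,
                    session=session,
                    trial=trial,
                    area=area,
                    label="target" if sub == "target" else "non_target",
                    sub_label=sub,
                    test_phase=test_phase,
                    dilution_exponent=dilution_exponent,
                    alerted=alerted,
                    segment_id=f"{profile.dog_id}_s{session:02d}_t{trial:02d}_{area}",
                )
            )
        t_cursor += visit_dur
    record = TrialRecord(
        dog_id=profile.dog_id, session=session, trial=trial, test_phase=test_phase,
        dilution_exponent=dilution_exponent, layout=layout,
        frames=pd.concat(frames_parts, ignore_index=True), events=events,
    )
    return record, segments


def _rotate_layout(rng: np.random.Generator, trial: int, test_phase: str) -> dict[str, str]:
    areas = list(AREA_BEHAVIOURS)
    target = areas[int(rng.integers(3))]
    rest = [a for a in areas if a != target]
    if test_phase == "test1":
        rng.shuffle(rest)
        return {target: "target", rest[0]: "distractor", rest[1]: "no_odour"}
    return {target: "target", rest[0]: "distractor", rest[1]: "distractor"}


def simulate_study(
    profiles: list[DogProfile],
    design: StudyDesign,
    noise: NoiseModel | None = None,
    test_phase: str = "test1",
    effect_steps=TEST2_EFFECT_STEPS,
) -> StudyDataset:
    """Simulate a full study.

    test1: ``design.sessions`` sessions of ``trials_per_session`` trials per
    dog at the trained concentration (dilution 10^-2), class effect
    ``design.effect_scale``; one target, one distractor, one no-odour area
    per trial, placement rotating pseudo-randomly.

    test2: one session per effect step (default 1, 0.5, 0.25, 0.1 mapping
    to dilution 10^-3 … 10^-6), one target and two distractor areas.
    Deterministic given ``design.seed``.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    noise = noise if noise is not None else NoiseModel()
    if test_phase == "test1":
        session_specs = [(s, design.effect_scale, TEST1_DILUTION_EXPONENT) for s in range(design.sessions)]
    elif test_phase == "test2":
        session_specs = [
            (s, es, TEST2_DILUTION_EXPONENTS[s] if s < len(TEST2_DILUTION_EXPONENTS) else -3 - s)
            for s, es in enumerate(effect_steps)
        ]
    else:
        raise ValueError(f"unknown test phase {test_phase!r}")

    all_segments, trials = [], []
    for dog_idx, profile in enumerate(profiles):
        for session, effect_scale, dilution in session_specs:
            lay_rng = np.random.default_rng(_trial_seed(design.seed, dog_idx, session, 9999))
            for trial in range(design.trials_per_session):
                mapping = _rotate_layout(lay_rng, trial, test_phase)
                p_alert = design.alert_prob(effect_scale)
                u = lay_rng.random()
                if u < p_alert:
                    outcome = "hit"
                elif u < p_alert + design.false_alert_prob:
                    outcome = "false_alert"
                else:
                    outcome = "miss"
                layout = TrialLayout(trial=trial, mapping=mapping, outcome=outcome)
                record, segments = simulate_trial(
                    profile, dog_idx, session, trial, design, noise, layout,
                    effect_scale, test_phase, dilution,
                )
                trials.append(record)
                all_segments.extend(segments)
    meta = tracking_io.segment_metadata(all_segments)
    meta["effect_scale"] = [
        design.effect_scale if test_phase == "test1"
        else effect_steps[s] for s in meta["session"]
    ] if len(meta) else []
    return StudyDataset(segments=all_segments, metadata=meta, trials=trials, profiles=profiles, design=design)


# ---------------------------------------------------------------------------
# writing a study to disk (tracking_io formats)
# ---------------------------------------------------------------------------

def write_study(dataset: StudyDataset, outdir) -> pd.DataFrame:
    """Write per-trial landmark tables, event logs and layouts plus the
    study metadata table; returns the trial index table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.trials:
        stem = f"{rec.dog_id}_s{rec.session:02d}_t{rec.trial:02d}"
        lm_path = outdir / f"{stem}_landmarks.csv"
        ev_path = outdir / f"{stem}_events.csv"
        tracking_io.write_landmark_table(rec.frames, lm_path)
        pd.DataFrame(
            [{"behaviour": e.behaviour, "start": e.start, "stop": e.stop} for e in rec.events]
        ).to_csv(ev_path, index=False)
        rows.append(
            {
                "dog_id": rec.dog_id, "session": rec.session, "trial": rec.trial,
                "test_phase": rec.test_phase, "dilution_exponent": rec.dilution_exponent,
                "outcome": rec.layout.outcome,
                **{f"layout_{a}": rec.layout.mapping[a] for a in AREA_BEHAVIOURS},
                "landmarks": lm_path.name, "events": ev_path.name,
            }
        )
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "trials.csv", index=False)
    tracking_io.write_metadata(dataset.segments, outdir / "segments_metadata.csv")
    return index


def simulate_expert_responses(
    video_ids: list[str],
    truth: dict[str, str],
    n_participants: int = 190,
    p_correct: float = 0.46,
    p_skip: float = 0.10,
    p_paid: float = 0.48,
    video_effect_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic expert-survey response table (one row per participant).

    Expert error is modelled as *video-correlated*: each clip carries a
    persuasiveness drawn in logit space (SD ``video_effect_sd``) around a
    base set by ``p_correct``, and every participant answers "target
    present" with that clip's probability (independently, skipping with
    ``p_skip``).  Some clips systematically mislead everyone — without
    this heterogeneity, pooling many near-chance judges into per-video
    vote fractions would amplify a slight per-answer anti-signal into a
    pooled AUC near 0, which is not how expert panels behave; at the
    default spread, per-answer accuracy ~0.46 pools to an AUC moderately
    below 0.5.  Columns: participant demographics plus one response
    column per video id with values in {target_present, target_absent,
    skipped}.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng(seed)
    p_present = {}
    for vid in video_ids:
        base = p_correct if truth[vid] == "target" else 1.0 - p_correct
        p_present[vid] = float(expit(logit(base) + rng.normal(0.0, video_effect_sd)))
    rows = []
    for p in range(n_participants):
        paid = rng.random() < p_paid
        row = {
            "participant_id": f"P{p:03d}",
            "age": int(rng.integers(18, 85)),
            "experience_category": "professional" if paid else "hobbyist",
            "paid_experience_years": float(rng.integers(1, 25)) if paid else 0.0,
            "continent": str(rng.choice(["Europe", "North America", "Asia", "Oceania"])),
        }
        for vid in video_ids:
            if rng.random() < p_skip:
                row[vid] = "skipped"
            else:
                row[vid] = "target_present" if rng.random() < p_present[vid] else "target_absent"
        rows.append(row)
    return pd.DataFrame(rows)
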