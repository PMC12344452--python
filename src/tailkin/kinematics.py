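"""Body-centred tail kinematics.

Transforms per-frame landmark positions into a dog-centred coordinate frame,
computes the signed tail angle theta, its angular velocity, a polar occupancy
histogram, and six per-segment kinematic features used throughout the
pipeline:

1. mean angle          — average signed tail angle over the search segment
2. amplitude positive  — extreme rightward excursion of theta (0 if the tail
                         never crosses to the dog's right)
3. amplitude negative  — extreme leftward excursion, reported as |min theta|
4. mean |velocity|     — average absolute angular velocity
5. sum positive        — fraction of valid frames with theta > 0
6. sum negative        — fraction of valid frames with theta < 0

Conventions
-----------
The body frame is centred on the tail base B with the +y axis running from
the shoulders S toward B; theta is the signed angle between that axis and
the tail-base→tail-middle vector, positive toward the dog's *right*.  In
y-down image coordinates viewed from directly overhead (``handedness =
"standard"``) the rightward unit vector is ``(-b_y, b_x)``; ``"mirrored"``
negates it for flipped footage.  Angles are degrees at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

LANDMARKS = ("nose", "front_head", "shoulders", "tail_base", "tail_middle", "tail_tip")

#: columns of a landmark-frame table, in canonical order
FRAME_COLUMNS = ("t",) + tuple(
    f"{lm}_{ax}" for lm in LANDMARKS for ax in ("x", "y")
) + ("conf",)

Handedness = Literal["standard", "mirrored"]


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunable knobs for angle extraction and feature computation."""

    handedness: Handedness = "standard"
    min_axis_px: float = 1.0          # |B - S| below this masks the frame
    conf_threshold: float = 0.5       # frames under this confidence are masked
    max_gap: int = 5                  # masked runs up to this length interpolated (in theta)
    velocity_mode: Literal["per_second", "per_frame"] = "per_second"
    n_sectors: int = 18               # polar histogram sectors over [-90, +90]


@dataclass
class BodyFrame:
    origin: np.ndarray        # (n, 2) tail-base positions
    axis_b: np.ndarray        # (n, 2) unit shoulders→tail-base
    axis_r: np.ndarray        # (n, 2) unit toward the dog's right
    valid: np.ndarray         # (n,) bool


@dataclass
class TailAngleSeries:
    t: np.ndarray             # (n,) seconds
    theta: np.ndarray         # (n,) degrees, NaN where invalid
    omega: np.ndarray         # (n,) deg/s (or deg/frame); omega[0] = NaN
    valid: np.ndarray         # (n,) bool, True where theta is usable
    omega_valid: np.ndarray   # (n,) bool, True where omega is usable

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class PolarHistogram:
    sector_edges: np.ndarray  # (n_sectors + 1,) degrees over [-90, +90]
    counts: np.ndarray        # (n_sectors,) occupancy
    n_frames: int


@dataclass
class KinematicProfile:
    mean_angle: float
    amp_positive: float
    amp_negative: float
    mean_abs_velocity: float
    sum_positive: float
    sum_negative: float
    n_valid_frames: int
    polar: PolarHistogram | None = field(default=None, repr=False)

    FEATURE_NAMES = (
        "mean_angle",
        "amp_positive",
        "amp_negative",
        "mean_abs_velocity",
        "sum_positive",
        "sum_negative",
    )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self.FEATURE_NAMES}
        d["n_valid_frames"] = self.n_valid_frames
        return d


class FeatureExtractionError(ValueError):
    """Raised when a segment has too few valid frames for features."""


# ---------------------------------------------------------------------------
# body frame and tail angle
# ---------------------------------------------------------------------------

def body_frame(
    shoulders: np.ndarray,
    tail_base: np.ndarray,
    handedness: Handedness = "standard",
    min_axis_px: float = 1.0,
) -> BodyFrame:
    """Build per-frame body frames from shoulders S and tail base B.

    ``axis_b = (B - S)/|B - S|``; ``axis_r = (-b_y, b_x)`` under standard
    image handedness (x right, y down, overhead view), negated when
    mirrored.  Frames with |B - S| <= ``min_axis_px`` or non-finite input
    are flagged invalid rather than raising.
    """
    S = np.atleast_2d(np.asarray(shoulders, dtype=float))
    B = np.atleast_2d(np.asarray(tail_base, dtype=float))
    if S.shape != B.shape or S.shape[1] != 2:
        raise ValueError("shoulders and tail_base must both be (n, 2)")
    d = B - S
    norm = np.hypot(d[:, 0], d[:, 1])
    finite = np.isfinite(d).all(axis=1)
    valid = finite & (norm > min_axis_px)
    axis_b = np.full_like(d, np.nan)
    with np.errstate(invalid="ignore"):
        axis_b[valid] = d[valid] / norm[valid, None]
    axis_r = np.stack([-axis_b[:, 1], axis_b[:, 0]], axis=1)
    if handedness == "mirrored":
        axis_r = -axis_r
    elif handedness != "standard":
        raise ValueError(f"unknown handedness: {handedness!r}")
    return BodyFrame(origin=B, axis_b=axis_b, axis_r=axis_r, valid=valid)


def tail_angle(tail_middle: np.ndarray, bf: BodyFrame) -> np.ndarray:
    """Signed tail angle theta in degrees, in (-180, 180].

    theta = atan2(BM·axis_r, BM·axis_b): 0 when the tail middle lies
    straight behind along the body axis, positive on the dog's right.
    Invalid body frames or missing tail middles give NaN.
    """
    M = np.atleast_2d(np.asarray(tail_middle, dtype=float))
    bm = M - bf.origin
    x = np.einsum("ij,ij->i", bm, bf.axis_r)
    y = np.einsum("ij,ij->i", bm, bf.axis_b)
    theta = np.degrees(np.arctan2(x, y))
    bad = ~bf.valid | ~np.isfinite(bm).all(axis=1)
    theta[bad] = np.nan
    return theta


def wrap_angle_diff(d: np.ndarray) -> np.ndarray:
    """Map angle differences (deg) into (-180, 180].

    Differences already in range pass through bit-exactly (the modulo
    detour through +180 would perturb them by an ulp, breaking the exact
    mirror antisymmetry wrap(-d) == -wrap(d) that the handedness
    invariant relies on).
    """
    d = np.asarray(d, dtype=float)
    wrapped = (d + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return np.where(np.abs(d) < 180.0, d, wrapped)


def angular_velocity(
    theta: np.ndarray,
    t: np.ndarray,
    mode: Literal["per_second", "per_frame"] = "per_second",
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive-frame angular velocity with wrap-around handling.

    Returns ``(omega, omega_valid)`` aligned with theta; ``omega[i]`` is the
    velocity over ``(i-1, i]`` and ``omega[0]`` is undefined.  Pairs that
    span a masked frame are masked.  ``per_second`` divides the wrapped
    difference by dt; ``per_frame`` reports the raw wrapped difference.
    """
    theta = np.asarray(theta, dtype=float)
    t = np.asarray(t, dtype=float)
    if theta.shape != t.shape:
        raise ValueError("theta and t must align")
    if valid is None:
        valid = np.isfinite(theta)
    n = theta.size
    omega = np.full(n, np.nan)
    ovalid = np.zeros(n, dtype=bool)
    if n < 2:
        return omega, ovalid
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing (duplicate or reversed t)")
    d = wrap_angle_diff(theta[1:] - theta[:-1])
    pair_ok = valid[1:] & valid[:-1]
    if mode == "per_second":
        omega[1:] = np.where(pair_ok, d / dt, np.nan)
    elif mode == "per_frame":
        omega[1:] = np.where(pair_ok, d, np.nan)
    else:
        raise ValueError(f"unknown velocity mode: {mode!r}")
    ovalid[1:] = pair_ok
    return omega, ovalid


# ---------------------------------------------------------------------------
# confidence masking and gap interpolation
# ---------------------------------------------------------------------------

def confidence_filter(
    theta: np.ndarray,
    t: np.ndarray,
    conf: np.ndarray,
    threshold: float = 0.5,
    max_gap: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask low-confidence frames and bridge short gaps in theta.

    Frames with confidence < threshold (or NaN theta) are masked; masked
    runs of length <= ``max_gap`` flanked by valid frames are filled by
    linear interpolation *of theta over time* (never of raw coordinates);
    longer runs, and runs touching either end, stay masked.
    Returns ``(theta_filled, valid)``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    theta = np.asarray(theta, dtype=float).copy()
    conf = np.asarray(conf, dtype=float)
    valid = np.isfinite(theta) & (conf >= threshold)
    theta[~valid] = np.nan
    if valid.all() or not valid.any():
        return theta, valid
    idx = np.flatnonzero(~valid)
    # group consecutive masked indices into runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= theta.size or run.size > max_gap:
            continue
        frac = (t[run] - t[lo]) / (t[hi] - t[lo])
        theta[run] = theta[lo] + frac * wrap_angle_diff(theta[hi] - theta[lo])
        valid[run] = True
    return theta, valid


# ---------------------------------------------------------------------------
# polar histogram
# ---------------------------------------------------------------------------

def polar_histogram(theta: np.ndarray, n_sectors: int = 18) -> PolarHistogram:
    """Occupancy histogram of theta over the semicircle [-90, +90].

    Equal-width sectors; angles outside the semicircle are clipped into the
    terminal sectors (a tail bent past +/-90 still counts as far right/left).
    Only finite theta values are counted.
    """
    if n_sectors < 2:
        raise ValueError("n_sectors must be >= 2")
    th = np.asarray(theta, dtype=float)
    th = th[np.isfinite(th)]
    edges = np.linspace(-90.0, 90.0, n_sectors + 1)
    width = 180.0 / n_sectors
    sector = np.floor((th + 90.0) / width).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    counts = np.bincount(sector, minlength=n_sectors)
    return PolarHistogram(sector_edges=edges, counts=counts, n_frames=int(th.size))


# ---------------------------------------------------------------------------
# per-segment pipeline
# ---------------------------------------------------------------------------

def tail_angle_series(frames: pd.DataFrame, config: KinematicsConfig | None = None) -> TailAngleSeries:
    """Landmark table → masked, gap-filled tail-angle series."""
    cfg = config or KinematicsConfig()
    t = frames["t"].to_numpy(dtype=float)
    S = frames[["shoulders_x", "shoulders_y"]].to_numpy(dtype=float)
    B = frames[["tail_base_x", "tail_base_y"]].to_numpy(dtype=float)
    M = frames[["tail_middle_x", "tail_middle_y"]].to_numpy(dtype=float)
    conf = frames["conf"].to_numpy(dtype=float) if "conf" in frames else np.ones(len(frames))
    bf = body_frame(S, B, handedness=cfg.handedness, min_axis_px=cfg.min_axis_px)
    theta = tail_angle(M, bf)
    theta, valid = confidence_filter(theta, t, conf, cfg.conf_threshold, cfg.max_gap)
    omega, ovalid = angular_velocity(theta, t, mode=cfg.velocity_mode, valid=valid)
    return TailAngleSeries(t=t, theta=theta, omega=omega, valid=valid, omega_valid=ovalid)


def features_from_series(series: TailAngleSeries, n_sectors: int = 18) -> KinematicProfile:
    """Six kinematic features + polar histogram from an angle series."""
    th = series.theta[series.valid]
    n = th.size
    if n < 2:
        raise FeatureExtractionError(f"only {n} valid frames; need >= 2")
    om = series.omega[series.omega_valid]
    pos = th[th > 0]
    neg = th[th < 0]
    return KinematicProfile(
        mean_angle=float(th.mean()),
        amp_positive=float(pos.max()) if pos.size else 0.0,
        amp_negative=float(-neg.min()) if neg.size else 0.0,
        mean_abs_velocity=float(np.abs(om).mean()) if om.size else 0.0,
        sum_positive=pos.size / n,
        sum_negative=neg.size / n,
        n_valid_frames=n,
        polar=polar_histogram(th, n_sectors),
    )


def extract_features(segment, config: KinematicsConfig | None = None) -> KinematicProfile:
    """Six per-segment kinematic features from a trajectory segment.

    ``segment`` is anything with a ``.frames`` landmark table (or the table
    itself).  Raises :class:`FeatureExtractionError` when fewer than two
    frames survive confidence filtering.
    """
    cfg = config or KinematicsConfig()
    frames = segment.frames if hasattr(segment, "frames") else segment
    series = tail_angle_series(frames, cfg)
    return features_from_series(series, n_sectors=cfg.n_sectors)


def feature_table(segments, config: KinematicsConfig | None = None) -> pd.DataFrame:
    """Feature rows (one per segment) with metadata columns attached.

    Segments that fail extraction (too few valid frames) are skipped and
    reported in the ``n_failed`` attribute of the returned frame.
    """
    rows, failed = [], 0
    for seg in segments:
        try:
            prof = extract_features(seg, config)
        except FeatureExtractionError:
            failed += 1
            continue
        row = {
            "segment_id": seg.segment_id,
            "dog_id": seg.dog_id,
            "session": seg.session,
            "trial": seg.trial,
            "area": seg.area,
            "label": seg.label,
            "sub_label": seg.sub_label,
            "test_phase": seg.test_phase,
            "dilution_exponent": seg.dilution_exponent,
            "alerted": seg.alerted,
        }
        row.update(prof.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = failed
    return df
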