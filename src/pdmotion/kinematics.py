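"""Kinematic channel construction from egocentric keypoint trajectories.

Each task defines a fixed enumeration of scalar *channels*: the Euclidean
norm of every hip-relative keypoint position and every three-point joint
angle (shoulder θs, elbow θe, wrist θw, and thumb θt for pronation–
supination), each in position / velocity / acceleration form (forward
differences), each unfiltered and Gaussian-filtered at widths 0.1 s and
0.2 s, and each scaled by its maximum absolute value.  This yields 72
channels for the finger-to-nose task (8 sources × 3 quantities × 3 filter
widths) and 90 for hand pronation–supination (10 sources).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .simulate import LabeledTrajectorySet, FTN_KEYPOINTS, HPS_KEYPOINTS

logger = logging.getLogger(__name__)

FILTER_WIDTHS = (0.0, 0.1, 0.2)
QUANTITIES = ("position", "velocity", "acceleration")

#: Joint-angle definitions as (A, vertex B, C) keypoint triples.
#: θt uses the wrist as vertex, between the wrist→finger and wrist→thumb
#: vectors — the only construction available from the tracked keypoints that
#: follows pronation–supination.
ANGLE_DEFS = {
    "theta_s": ("hip", "shoulder", "elbow"),
    "theta_e": ("shoulder", "elbow", "wrist"),
    "theta_w": ("elbow", "wrist", "finger"),
    "theta_t": ("finger", "wrist", "thumb"),
}

FTN_ANGLES = ("theta_s", "theta_e", "theta_w")
HPS_ANGLES = FTN_ANGLES + ("theta_t",)


@dataclass(frozen=True, order=True)
class ChannelKey:
    """Identity of one scalar kinematic channel."""

    source: str                # keypoint name or joint-angle name
    quantity: str              # position | velocity | acceleration
    filter_width_s: float      # 0.0 (unfiltered), 0.1 or 0.2

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.filter_width_s not in FILTER_WIDTHS:
            raise ValueError(f"filter width must be one of {FILTER_WIDTHS}")

    @property
    def name(self) -> str:
        return f"{self.source}.{self.quantity}.{self.filter_width_s:.1f}"

    @classmethod
    def from_name(cls, name: str) -> "ChannelKey":
        source, quantity, w_int, w_frac = name.split(".")
        return cls(source=source, quantity=quantity, filter_width_s=float(f"{w_int}.{w_frac}"))


@dataclass
class ChannelSet:
    """The enumerated scaled kinematic channels of one video."""

    channels: dict[ChannelKey, np.ndarray]
    fps: float
    task: str

    def __getitem__(self, key: ChannelKey) -> np.ndarray:
        return self.channels[key]

    def __len__(self) -> int:
        return len(self.channels)

    def keys_for(self, quantity: str | None = None, filter_width_s: float | None = None):
        return [
            k
            for k in self.channels
            if (quantity is None or k.quantity == quantity)
            and (filter_width_s is None or k.filter_width_s == filter_width_s)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Wide table, one column per channel (shorter series NaN-padded)."""
        return pd.DataFrame({k.name: pd.Series(v) for k, v in sorted(self.channels.items())})


def egocentric_transform(t: LabeledTrajectorySet) -> LabeledTrajectorySet:
    """Re-express every keypoint relative to the same-side hip, per frame.

    Removes whole-body translation (and camera translation); the hip maps to
    the origin.  Idempotent.
    """
    if "hip" not in t.trajectories:
        raise ValueError("missing hip keypoint; cannot build egocentric frame")
    hip = t.trajectories["hip"]
    out = t.copy()
    for name in out.trajectories:
        out.trajectories[name] = out.trajectories[name] - hip
    return out


def joint_angle(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray | float:
    """Angle at vertex B between limb vectors A−B and C−B, in radians.

    cos θ is the normalized dot product, clamped to [−1, 1]; θ ∈ [0, π].
    Accepts single points (shape (3,)) or per-frame series (n, 3).
    Zero-length limb vectors yield NaN for the affected frames rather than
    raising; callers interpolate.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    scalar = A.ndim == 1
    ab = np.atleast_2d(A - B)
    cb = np.atleast_2d(C - B)
    na = np.linalg.norm(ab, axis=1)
    nc = np.linalg.norm(cb, axis=1)
    denom = na * nc
    bad = denom == 0.0
    if np.any(bad):
        logger.warning("joint_angle: %d degenerate frame(s) with zero-length limb vector", bad.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", ab, cb) / denom
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[bad] = np.nan
    return float(ang[0]) if scalar else ang


def scalarize_position(traj: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean norm of a hip-relative 3D trajectory."""
    return np.linalg.norm(np.asarray(traj, dtype=float), axis=-1)


def forward_difference(x: np.ndarray, order: int, fps: float) -> np.ndarray:
    """Forward-difference derivative: order 1 → velocity, order 2 → acceleration.

    v_t = (x_{t+1} − x_t)·fps (length N−1);
    a_t = (x_{t+2} − 2 x_{t+1} + x_t)·fps² (length N−2).
    """
    x = np.asarray(x, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if len(x) <= order:
        raise ValueError(f"series of length {len(x)} too short for order-{order} difference")
    return np.diff(x, n=order) * fps**order


def gaussian_filter(x: np.ndarray, width_s: float, fps: float) -> np.ndarray:
    """Smooth with a unit-sum Gaussian kernel of σ = width_s·fps samples.

    Kernel truncated at 4σ; reflected boundaries; output length equals
    input length.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma=width_s * fps,
                             mode="reflect", truncate=4.0)


def maxabs_scale(x: np.ndarray) -> np.ndarray:
    """Divide by the maximum absolute value; all-zero input is returned as is."""
    x = np.asarray(x, dtype=float)
    m = np.nanmax(np.abs(x)) if len(x) else 0.0
    if not np.isfinite(m) or m == 0.0:
        return x.copy()
    return x / m


def _interpolate_nan(x: np.ndarray, label: str) -> np.ndarray:
    """Linearly interpolate missing samples (degenerate frames), with a log."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        logger.warning("%s: all frames degenerate; channel left as zeros", label)
        return np.zeros_like(x)
    logger.info("%s: interpolating %d degenerate frame(s)", label, int(bad.sum()))
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def task_sources(task: str) -> tuple[str, ...]:
    """Enumerated signal sources for a task: keypoints then joint angles."""
    if task == "HPS":
        return HPS_KEYPOINTS + HPS_ANGLES
    return FTN_KEYPOINTS + FTN_ANGLES


def build_channel_set(t: LabeledTrajectorySet) -> ChannelSet:
    """Build the full scaled channel enumeration for one video.

    Filtering is applied to the base position/angle signal before
    differentiation, so the filtered velocity/acceleration variants are the
    derivatives of the corresponding filtered positions.  Every channel is
    max-abs scaled last.
    """
    ego = egocentric_transform(t)
    required = HPS_KEYPOINTS if t.task == "HPS" else FTN_KEYPOINTS
    for kp in required:
        if kp not in ego.trajectories:
            raise ValueError(f"missing required keypoint {kp!r} for task {t.task}")

    base_signals: dict[str, np.ndarray] = {}
    for kp in required:
        base_signals[kp] = scalarize_position(ego.trajectories[kp])
    for angle in (HPS_ANGLES if t.task == "HPS" else FTN_ANGLES):
        a, b, c = ANGLE_DEFS[angle]
        series = joint_angle(ego.trajectories[a], ego.trajectories[b], ego.trajectories[c])
        base_signals[angle] = _interpolate_nan(np.asarray(series), angle)

    channels: dict[ChannelKey, np.ndarray] = {}
    for source, base in base_signals.items():
        for width in FILTER_WIDTHS:
            sig = base if width == 0.0 else gaussian_filter(base, width, t.fps)
            channels[ChannelKey(source, "position", width)] = maxabs_scale(sig)
            channels[ChannelKey(source, "velocity", width)] = maxabs_scale(
                forward_difference(sig, 1, t.fps)
            )
            channels[ChannelKey(source, "acceleration", width)] = maxabs_scale(
                forward_difference(sig, 2, t.fps)
            )
    return ChannelSet(channels=channels, fps=t.fps, task=t.task)
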