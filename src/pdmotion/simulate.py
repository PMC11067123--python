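"""Synthetic keypoint-trajectory generator for the FTN and HPS clinical tasks.

The generator produces per-frame 3D positions of upper-limb keypoints
(hip, shoulder, elbow, wrist, finger, and — for pronation–supination — thumb)
as a pose-estimation system would, in an arbitrary world frame.  Movement is
driven by a phase variable whose instantaneous frequency can decline over
time (the bradykinetic *sequence effect*), with per-cycle peak-amplitude
decrement, dwell pauses held at the movement extrema, superimposed tremor,
and i.i.d. keypoint measurement jitter.  A rigid view transform emulates a
change of camera perspective.

The arm is modelled as a two-link planar-dominant kinematic chain
(shoulder–elbow–wrist) with the hand rigidly attached; for HPS the hand
rotates about the forearm axis.  Lengths are in arbitrary units — only
relative signals survive downstream max-abs scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TASKS = ("FTN", "HPS")
FTN_KEYPOINTS = ("hip", "shoulder", "elbow", "wrist", "finger")
HPS_KEYPOINTS = FTN_KEYPOINTS + ("thumb",)

#: Symptom-mechanism thresholds used by the generator's severity mapping.
#: A mechanism counts toward the severity score when its parameter crosses
#: the threshold in the symptomatic direction.
SYMPTOM_THRESHOLDS = {
    "freq_slope_hz_per_s": -0.02,   # at or below → sequence effect present
    "amp_decrement_per_cycle": 0.02,  # at or above → amplitude decrement
    "pause_dwell_s": 0.15,          # at or above → movement pauses
    "tremor_amp": 0.01,             # at or above → tremor
}

#: Magnitudes used by :func:`simulate_cohort` when a mechanism is active.
#: These represent strong, clinically evident symptom expression.
SYMPTOM_STRENGTH = {
    "freq_slope_hz_per_s": -0.05,
    "amp_decrement_per_cycle": 0.05,
    "pause_dwell_s": 0.4,
    "tremor_amp": 0.02,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated task performance.

    Durations are seconds, frequencies Hz, positions arbitrary length units.
    Defaults describe an asymptomatic performance of the median-length video
    (19 s at 30 fps, ~1 Hz repetition rate).
    """

    task: str = "FTN"
    duration_s: float = 19.0
    fps: float = 30.0
    base_freq_hz: float = 1.0
    freq_slope_hz_per_s: float = 0.0
    amp_decrement_per_cycle: float = 0.0
    pause_dwell_s: float = 0.0
    tremor_freq_hz: float = 5.0
    tremor_amp: float = 0.0
    noise_sd: float = 0.0
    segment_lengths: tuple[float, float, float] = (0.30, 0.25, 0.08)
    seed: int = 0
    side: str = "right"
    participant_id: str = "P000"
    assessment_index: int = 1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0.0 <= self.amp_decrement_per_cycle < 1.0:
            raise ValueError("amp_decrement_per_cycle must be in [0, 1)")
        if self.pause_dwell_s < 0:
            raise ValueError("pause_dwell_s must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.base_freq_hz <= 0:
            raise ValueError("base_freq_hz must be positive")
        if len(self.segment_lengths) != 3 or any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment_lengths must be three positive lengths")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class LabeledTrajectorySet:
    """One video's 3D keypoint time series plus clinical metadata.

    ``trajectories`` maps keypoint name → (n_frames, 3) array of positions.
    ``sma_score`` is the clinician severity rating, 0 (no symptoms) to 4.
    """

    trajectories: dict[str, np.ndarray]
    fps: float
    task: str
    side: str = "right"
    participant_id: str = "P000"
    assessment_index: int = 1
    sma_score: int = 0

    def __post_init__(self) -> None:
        lengths = {k: len(v) for k, v in self.trajectories.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"keypoint sequences differ in length: {lengths}")
        required = HPS_KEYPOINTS if self.task == "HPS" else FTN_KEYPOINTS
        missing = [k for k in required if k not in self.trajectories]
        if missing:
            raise ValueError(f"task {self.task} requires keypoints {missing}")
        if self.sma_score not in (0, 1, 2, 3, 4):
            raise ValueError("sma_score must be an integer in 0..4")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.trajectories.values())))

    @property
    def keypoints(self) -> tuple[str, ...]:
        return tuple(self.trajectories)

    def copy(self) -> "LabeledTrajectorySet":
        return LabeledTrajectorySet(
            trajectories={k: v.copy() for k, v in self.trajectories.items()},
            fps=self.fps,
            task=self.task,
            side=self.side,
            participant_id=self.participant_id,
            assessment_index=self.assessment_index,
            sma_score=self.sma_score,
        )


def severity_score(config: SimConfig) -> int:
    """Number of symptom mechanisms active in ``config``, capped at 4.

    The score is 0 iff every symptom parameter is at its asymptomatic
    default.  This mapping is a reproducible stand-in for a clinical
    severity rating, not a clinical claim.
    """
    n = 0
    if config.freq_slope_hz_per_s <= SYMPTOM_THRESHOLDS["freq_slope_hz_per_s"]:
        n += 1
    if config.amp_decrement_per_cycle >= SYMPTOM_THRESHOLDS["amp_decrement_per_cycle"]:
        n += 1
    if config.pause_dwell_s >= SYMPTOM_THRESHOLDS["pause_dwell_s"]:
        n += 1
    if config.tremor_amp >= SYMPTOM_THRESHOLDS["tremor_amp"]:
        n += 1
    return min(n, 4)


def _phase_series(config: SimConfig) -> np.ndarray:
    """Movement phase per frame; pauses hold phase at each half-cycle extremum."""
    n = int(round(config.duration_s * config.fps))
    dt = 1.0 / config.fps
    floor_hz = 0.05  # frequency never declines below this
    phi = 0.0
    dwell_left = 0.0
    next_extremum = np.pi
    out = np.empty(n)
    for i in range(n):
        out[i] = phi
        if dwell_left > 0.0:
            dwell_left -= dt
            continue
        f = max(config.base_freq_hz + config.freq_slope_hz_per_s * i * dt, floor_hz)
        dphi = 2.0 * np.pi * f * dt
        if config.pause_dwell_s > 0.0 and phi + dphi >= next_extremum:
            phi = next_extremum
            next_extremum += np.pi
            dwell_left = config.pause_dwell_s - dt
        else:
            phi += dphi
    return out


def _rotate_in_plane(v: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate (n, 3) vectors by per-frame angles about the +z axis."""
    c, s = np.cos(angle), np.sin(angle)
    out = np.empty_like(v)
    out[:, 0] = c * v[:, 0] - s * v[:, 1]
    out[:, 1] = s * v[:, 0] + c * v[:, 1]
    out[:, 2] = v[:, 2]
    return out


def simulate_task_trajectories(config: SimConfig) -> LabeledTrajectorySet:
    """Generate one labeled task performance from ``config``.

    Deterministic given ``config.seed``.  Raises if the video is shorter
    than a single movement cycle.
    """
    if config.duration_s < 1.0 / config.base_freq_hz:
        raise ValueError("degenerate duration: shorter than one movement cycle")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fps))
    t = np.arange(n) / config.fps
    l1, l2, l3 = config.segment_lengths

    phi = _phase_series(config)
    # Smooth per-cycle amplitude decrement: successive peaks shrink by the
    # configured fraction per completed repetition.
    amp = (1.0 - config.amp_decrement_per_cycle) ** (phi / (2.0 * np.pi))

    # Body frame: x forward, y up, z lateral. The whole body drifts slowly
    # (handheld camera / postural sway); removed by the egocentric transform.
    body_offset = np.array([0.5, 0.9, 2.0])
    sway = 0.005 * np.stack(
        [np.sin(2 * np.pi * 0.2 * t), np.zeros(n), np.cos(2 * np.pi * 0.17 * t)], axis=1
    )
    hip = np.zeros((n, 3)) + body_offset + sway

    if config.task == "FTN":
        # Excursion 0 (flexed, finger at nose) → amp (full extension).
        exc = amp * 0.5 * (1.0 - np.cos(phi))
        alpha = 0.25 + 0.55 * exc                # upper-arm angle from vertical
        theta_e = 0.7 + 2.1 * exc                # interior elbow angle
        gamma_w = 0.35 + 0.25 * exc              # hand flexion from forearm axis
        hand_spin = np.zeros(n)
    else:
        # Arm held out; hand alternately pronates/supinates with the phase.
        wob = amp * np.cos(phi)
        exc = wob
        alpha = 1.35 + 0.03 * wob
        theta_e = 2.7 + 0.08 * wob
        gamma_w = 0.25 + 0.12 * amp * np.sin(phi)
        hand_spin = 1.3 * wob                    # pronation–supination angle

    # Compensatory trunk lean: the shoulder shifts slightly with the reach.
    shoulder = hip + np.stack(
        [0.02 * exc, np.full(n, 0.45), 0.01 * exc], axis=1
    )

    up_dir = np.stack([np.sin(alpha), -np.cos(alpha), np.zeros(n)], axis=1)
    elbow = shoulder + l1 * up_dir
    # Forearm makes interior angle theta_e with the upper arm.
    fore_dir = _rotate_in_plane(up_dir, -(np.pi - theta_e))
    # Slight out-of-plane component so trajectories are genuinely 3D.
    fore_dir[:, 2] += 0.15
    fore_dir /= np.linalg.norm(fore_dir, axis=1, keepdims=True)
    wrist = elbow + l2 * fore_dir

    # Orthonormal frame about the forearm axis for the hand segment.
    ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(fore_dir, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(fore_dir, u)

    def _cone(axis_angle: np.ndarray, spin: np.ndarray, length: float) -> np.ndarray:
        radial = (
            np.cos(spin)[:, None] * u + np.sin(spin)[:, None] * v
        )
        d = np.cos(axis_angle)[:, None] * fore_dir + np.sin(axis_angle)[:, None] * radial
        return wrist + length * d

    finger = _cone(gamma_w, hand_spin, l3)
    points = {"hip": hip, "shoulder": shoulder, "elbow": elbow, "wrist": wrist, "finger": finger}
    if config.task == "HPS":
        points["thumb"] = _cone(np.full(n, 0.9), hand_spin + 1.2, 0.6 * l3)

    if config.tremor_amp > 0.0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        osc = np.sin(2 * np.pi * config.tremor_freq_hz * t + rng.uniform(0, 2 * np.pi))
        tremor = config.tremor_amp * osc[:, None] * direction
        for name, scale in (("elbow", 0.3), ("wrist", 1.0), ("finger", 1.0), ("thumb", 1.0)):
            if name in points:
                points[name] = points[name] + scale * tremor

    if config.noise_sd > 0.0:
        for name in points:
            points[name] = points[name] + rng.normal(0.0, config.noise_sd, size=(n, 3))

    if config.side == "left":  # mirror laterally
        for name in points:
            points[name] = points[name] * np.array([1.0, 1.0, -1.0])

    keys = HPS_KEYPOINTS if config.task == "HPS" else FTN_KEYPOINTS
    return LabeledTrajectorySet(
        trajectories={k: points[k] for k in keys},
        fps=config.fps,
        task=config.task,
        side=config.side,
        participant_id=config.participant_id,
        assessment_index=config.assessment_index,
        sma_score=severity_score(config),
    )


_MECHANISMS = tuple(SYMPTOM_STRENGTH)


def _normalize_mix(severity_mix) -> np.ndarray:
    if isinstance(severity_mix, Mapping):
        mix = np.zeros(5)
        for score, p in severity_mix.items():
            mix[int(score)] = float(p)
    else:
        mix = np.asarray(list(severity_mix), dtype=float)
        if mix.size > 5:
            raise ValueError("severity_mix has more than five scores")
        mix = np.pad(mix, (0, 5 - mix.size))
    if mix.size == 0 or not np.any(mix):
        raise ValueError("severity_mix is empty")
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("severity_mix must be non-negative and sum to 1")
    return mix / mix.sum()


def simulate_cohort(
    n_participants: int,
    assessments_per_participant: int,
    severity_mix,
    seed: int,
    task: str = "FTN",
    base_config: SimConfig | None = None,
) -> list[LabeledTrajectorySet]:
    """Simulate a cohort of repeated task assessments.

    Each participant keeps a stable identity (limb lengths, preferred
    movement rate, side) across assessments, while symptom severity is
    redrawn from ``severity_mix`` per assessment, mimicking changing
    medication state.  For a drawn score *s*, *s* of the four symptom
    mechanisms (sequence effect, amplitude decrement, pauses, tremor) are
    activated at strong magnitudes, so the generator's severity mapping
    reproduces *s* exactly.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if assessments_per_participant < 1:
        raise ValueError("need at least 1 assessment per participant")
    mix = _normalize_mix(severity_mix)
    base = base_config or SimConfig(task=task)
    rng = np.random.default_rng(seed)

    cohort: list[LabeledTrajectorySet] = []
    for p in range(n_participants):
        pid = f"P{p:03d}"
        l1 = base.segment_lengths[0] * rng.uniform(0.92, 1.08)
        l2 = base.segment_lengths[1] * rng.uniform(0.92, 1.08)
        l3 = base.segment_lengths[2] * rng.uniform(0.92, 1.08)
        freq = base.base_freq_hz * rng.uniform(0.85, 1.25)
        side = "right" if rng.random() < 0.8 else "left"
        for a in range(1, assessments_per_participant + 1):
            score = int(rng.choice(5, p=mix))
            active = list(rng.permutation(_MECHANISMS)[:score])
            scale = 1.0 + 0.15 * max(score - 1, 0)
            params = {
                name: SYMPTOM_STRENGTH[name] * scale if name in active else 0.0
                for name in _MECHANISMS
            }
            cfg = replace(
                base,
                base_freq_hz=freq,
                segment_lengths=(l1, l2, l3),
                side=side,
                participant_id=pid,
                assessment_index=a,
                seed=int(rng.integers(0, 2**31 - 1)),
                **params,
            )
            traj = simulate_task_trajectories(cfg)
            assert traj.sma_score == score  # mapping consistent by construction
            cohort.append(traj)
    return cohort


def perturb_view(
    t: LabeledTrajectorySet,
    rotation: np.ndarray,
    translation: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LabeledTrajectorySet:
    """Apply one rigid camera-view change plus i.i.d. keypoint jitter.

    ``rotation`` must be a proper rigid rotation matrix (orthogonal,
    determinant +1).  The same transform is applied to every keypoint at
    every frame, emulating a different recording perspective.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("rotation must be a proper rigid rotation (R Rᵀ = I, det = +1)")
    tr = np.asarray(translation, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    out = t.copy()
    for name, xyz in out.trajectories.items():
        moved = xyz @ R.T + tr
        if noise_sd > 0.0:
            moved = moved + rng.normal(0.0, noise_sd, size=moved.shape)
        out.trajectories[name] = moved
    return out
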