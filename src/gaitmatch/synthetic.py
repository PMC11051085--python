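"""Seeded synthetic gait cohorts for end-to-end testing.

Real multi-view gait corpora (CASIA-B, OUMVLP-Pose) are access-restricted,
so this module generates cohorts with the statistical structure the
matching pipeline assumes: N subjects × V camera views × two independent
walking bouts per subject (one reference, one target), each a T-frame
sequence of periodic joint kinematics.

Per subject, each joint angle follows a sinusoid

    theta_j(t) = mean_j + amp_j * sin(2 pi f t + phase_j) + eps,
    eps ~ N(0, sigma_view^2),  clipped to [0, 180] degrees,

with subject-specific stride frequency f, per-angle means, amplitudes and
phase lags; right-side angles run in antiphase (a pi offset plus a
subject-specific perturbation), which reproduces normal gait symmetry and
the strong off-diagonal rank correlations between joints. The target bout
of a subject shares the kinematic parameters but uses independent noise
and a random global phase offset, emulating a second, unsynchronized
walk past the cameras. The view effect is additive per-view noise, enough
to make per-view decisions heterogeneous and the majority vote
meaningful; no camera projection is modelled.

A planar kinematic chain embeds the simulated angles into canonical-16
landmark coordinates, so the pose-reading and angle-extraction stages can
be exercised end to end: extracting angles from the noiseless embedding
reproduces the generating angles to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import ConfigurationError
from .kinematics import MEDIAPIPE_ANGLE_SET, JointAngleSeries
from .pose_io import CANONICAL16_NAMES, PoseSequence

ANGLE_NAMES = tuple(d.name for d in MEDIAPIPE_ANGLE_SET)

#: CASIA-B-style view labels: 0..180 degrees at 18-degree intervals.
DEFAULT_VIEWS = tuple(str(v) for v in range(0, 181, 18))

#: Per-view angle-noise SD (degrees) calibrated so that single-view
#: matching on the default 20-subject cohort lands near 60% accuracy —
#: the moderate-difficulty regime where cross-view voting has room to
#: help without being saturated.
MODERATE_VIEW_NOISE_SD = 19.0

# Physiological baseline per angle: (mean degrees, amplitude degrees,
# within-stride phase lag radians). Left/right pairs share the baseline;
# the right side is shifted by pi at sampling time.
_BASELINES = {
    "LElbow": (155.0, 8.0, 0.0), "RElbow": (155.0, 8.0, 0.0),
    "LHip": (155.0, 10.0, 0.3), "RHip": (155.0, 10.0, 0.3),
    "LKnee": (140.0, 22.0, 1.0), "RKnee": (140.0, 22.0, 1.0),
    "LAnkleFront": (115.0, 12.0, 1.7), "RAnkleFront": (115.0, 12.0, 1.7),
    "LAnkleBack": (95.0, 10.0, 1.9), "RAnkleBack": (95.0, 10.0, 1.9),
}

# Planar chain segment lengths (metres) and root positions used by the
# landmark embedding. Absolute scale is irrelevant downstream.
_SEGMENTS = {"thigh": 0.45, "shank": 0.45, "foot": 0.18, "heel": 0.08,
             "upper_arm": 0.30, "forearm": 0.28}
_ROOTS = {
    "left_hip": (0.09, 1.00), "right_hip": (-0.09, 1.00),
    "left_shoulder": (0.13, 1.55), "right_shoulder": (-0.13, 1.55),
}


@dataclass(frozen=True)
class GaitModelParams:
    """One subject's kinematic parameters (J = 10 whole-body angles)."""

    subject_id: str
    frequency: float              # stride cycles per frame
    means: np.ndarray             # (J,) degrees
    amplitudes: np.ndarray        # (J,) degrees
    phases: np.ndarray            # (J,) radians, antiphase already applied

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        if np.any(self.amplitudes < 0):
            raise ConfigurationError("amplitudes must be non-negative")
        if not 0.0 < self.frequency < 0.5:
            raise ConfigurationError("frequency must lie in (0, 0.5) cycles/frame")
        lo = self.means - self.amplitudes
        hi = self.means + self.amplitudes
        if np.any(lo < 0.0) or np.any(hi > 180.0):
            raise ConfigurationError("mean +/- amplitude must stay within [0, 180] degrees")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the small-corpus regime the pipeline targets: 20
    subjects, the 11 frontal-to-rear views, 100-frame bouts.
    """

    n_subjects: int = 20
    views: tuple[str, ...] = DEFAULT_VIEWS
    n_frames: int = 100
    view_noise_sd: float = 0.0        # degrees, per-view additive angle noise
    landmark_jitter_sd: float = 0.0   # metres, landmark coordinate noise
    mean_spread: float = 8.0          # degrees, subject offset around baseline means
    amplitude_scale: tuple[float, float] = (0.7, 1.3)
    frequency_range: tuple[float, float] = (0.03, 0.06)
    phase_spread: float = 0.5         # radians, subject offset around baseline lags

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.view_noise_sd < 0 or self.landmark_jitter_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if len(set(self.views)) != len(self.views):
            raise ConfigurationError("view labels must be unique")
        lo, hi = self.frequency_range
        if not (0.0 < lo <= hi < 0.5):
            raise ConfigurationError("frequency_range must lie within (0, 0.5)")
        worst_amp = np.array([_BASELINES[n][1] for n in ANGLE_NAMES]) * self.amplitude_scale[1]
        means = np.array([_BASELINES[n][0] for n in ANGLE_NAMES])
        if np.any(means + self.mean_spread + worst_amp > 180.0) or np.any(
            means - self.mean_spread - worst_amp < 0.0
        ):
            raise ConfigurationError(
                "mean_spread/amplitude_scale allow angles outside [0, 180]"
            )


def sample_cohort(config: CohortConfig, seed: int) -> list[GaitModelParams]:
    """Draw subject parameter sets; deterministic for a fixed seed.

    Leg angles on the right side run in strict antiphase (a pi offset),
    as in normal gait. Arm-swing timing, by contrast, is the most
    idiosyncratic part of a walking pattern, and it is all that the
    two-angle upper-body features can see, so elbow parameters are laid
    out to keep subjects identifiable in the noiseless limit rather than
    left to independent draws (which collide for some cohorts):

    * the left-right elbow rank correlation is stratified across the
      cohort — evenly spaced targets, randomly assigned to subjects,
      realized by numerically inverting the phase-gap-to-correlation map
      at each subject's stride frequency — so the rank feature separates
      every pair;
    * the two elbow mean angles are assigned from a space-filling grid
      over the mean-spread square (random subset, random assignment), so
      every pair of subjects is separated by a guaranteed margin in
      elbow posture that time warping cannot remove.
    """
    from .correlation import spearman_pair

    rng = np.random.default_rng(seed)
    n = config.n_subjects
    T = config.n_frames
    # stratified elbow-correlation targets, one stratum per subject
    rho_targets = (-0.92 + 1.84 * (np.arange(n) + 0.5) / n)[rng.permutation(n)]
    # space-filling grid of (LElbow, RElbow) mean offsets, one per subject
    rows = int(np.ceil(np.sqrt(n)))
    cols = int(np.ceil(n / rows))
    s = config.mean_spread
    xs = np.linspace(-s, s, cols) if cols > 1 else np.array([0.0])
    ys = np.linspace(-s, s, rows) if rows > 1 else np.array([0.0])
    grid = np.array([(x, y) for y in ys for x in xs])
    elbow_mean_offsets = grid[rng.permutation(len(grid))[:n]]
    gap_grid = np.linspace(0.0, np.pi, 181)
    rho_maps: dict[int, np.ndarray] = {}

    def elbow_gap_for(n_cycles: int, rho_target: float) -> float:
        if n_cycles not in rho_maps:
            theta = 2 * np.pi * n_cycles * np.arange(T) / T
            rho_maps[n_cycles] = np.array([
                spearman_pair(np.sin(theta), np.sin(theta + d)) for d in gap_grid
            ])
        rho = rho_maps[n_cycles]  # decreasing in the gap
        return float(np.interp(rho_target, rho[::-1], gap_grid[::-1]))

    subjects = []
    for i in range(n):
        # whole number of stride cycles per bout: sampling a periodic
        # signal over complete cycles makes its value multiset invariant
        # to integer-frame time shifts (no spectral leakage), so bout
        # statistics depend on the subject, not on when the bout starts.
        # Cycle counts coprime with T are preferred: they visit T distinct
        # stride phases, giving rank statistics their finest resolution.
        lo = int(np.ceil(config.frequency_range[0] * T))
        hi = int(np.floor(config.frequency_range[1] * T))
        candidates = list(range(lo, max(lo, hi) + 1))
        coprime = [k for k in candidates if np.gcd(k, T) == 1]
        n_cycles = int(rng.choice(coprime or candidates))
        means, amps, phases = [], [], []
        for name in ANGLE_NAMES:
            base_mean, base_amp, base_lag = _BASELINES[name]
            if name == "LElbow":
                means.append(base_mean + elbow_mean_offsets[i, 0])
            elif name == "RElbow":
                means.append(base_mean + elbow_mean_offsets[i, 1])
            else:
                means.append(base_mean + rng.uniform(-config.mean_spread, config.mean_spread))
            amps.append(base_amp * rng.uniform(*config.amplitude_scale))
            lag = base_lag + rng.uniform(-config.phase_spread, config.phase_spread)
            if name == "RElbow":
                lag = phases[ANGLE_NAMES.index("LElbow")] + elbow_gap_for(
                    n_cycles, rho_targets[i])
            elif name.startswith("R"):
                lag += np.pi  # left-right antiphase of normal gait
            phases.append(lag)
        subjects.append(GaitModelParams(
            subject_id=f"s{i:03d}",
            frequency=n_cycles / config.n_frames,
            means=np.array(means),
            amplitudes=np.array(amps),
            phases=np.array(phases),
        ))
    return subjects


def simulate_angle_series(
    params: GaitModelParams,
    view: str,
    sequence_role: Literal["reference", "target"] = "reference",
    seed: int = 0,
    n_frames: int = 100,
    noise_sd: float = 0.0,
    phase_offset: float | None = None,
) -> JointAngleSeries:
    """One walking bout as a T × 10 angle matrix.

    A ``target`` bout draws a random global phase offset (an independent
    walk starts at an arbitrary point of the stride cycle) unless
    ``phase_offset`` is given explicitly. The offset is a random
    integer-frame time shift, so a noiseless target is a circularly
    shifted copy of the periodic reference trajectory.
    """
    rng = np.random.default_rng(seed)
    if phase_offset is None:
        if sequence_role == "reference":
            phase_offset = 0.0
        else:
            shift = int(rng.integers(0, n_frames))
            phase_offset = 2 * np.pi * params.frequency * shift
    t = np.arange(n_frames)[:, None]
    phases = params.phases[None, :] + phase_offset
    clean = params.means[None, :] + params.amplitudes[None, :] * np.sin(
        2 * np.pi * params.frequency * t + phases
    )
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    return JointAngleSeries(
        values=np.clip(noisy, 0.0, 180.0),
        angle_names=list(ANGLE_NAMES),
        subject_id=params.subject_id,
        view=str(view),
    )


def _rot(vec: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Rotate planar vectors (T, 2) by per-frame angles (T,)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.stack([c * vec[:, 0] - s * vec[:, 1],
                     s * vec[:, 0] + c * vec[:, 1]], axis=1)


def embed_angles_as_pose(angles: JointAngleSeries, jitter_sd: float = 0.0,
                         seed: int = 0) -> PoseSequence:
    """Place canonical-16 landmarks realizing the given angle series.

    A fixed planar skeleton (hips and shoulders at constant positions,
    constant segment lengths) is articulated so that each interior angle
    at elbow/hip/knee/ankle equals the requested value; the law-of-cosines
    extraction therefore recovers the inputs exactly in the jitter-free
    case.
    """
    T = angles.n_frames
    rad = {name: np.radians(angles.column(name)) for name in angles.angle_names}
    coords = {}
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        S = side[0].upper()
        hip = np.tile(_ROOTS[f"{side}_hip"], (T, 1))
        shoulder = np.tile(_ROOTS[f"{side}_shoulder"], (T, 1))
        # leg chain: knee direction from the hip makes the hip angle with
        # the hip->shoulder direction; sign mirrors left/right
        u_hs = (shoulder - hip) / np.linalg.norm(shoulder - hip, axis=1, keepdims=True)
        knee = hip + _SEGMENTS["thigh"] * _rot(u_hs, sgn * rad[f"{S}Hip"])
        u_kh = (hip - knee) / np.linalg.norm(hip - knee, axis=1, keepdims=True)
        ankle = knee + _SEGMENTS["shank"] * _rot(u_kh, sgn * rad[f"{S}Knee"])
        u_ak = (knee - ankle) / np.linalg.norm(knee - ankle, axis=1, keepdims=True)
        if f"{S}AnkleFront" in rad:
            foot = ankle + _SEGMENTS["foot"] * _rot(u_ak, sgn * rad[f"{S}AnkleFront"])
            heel = ankle + _SEGMENTS["heel"] * _rot(u_ak, -sgn * rad[f"{S}AnkleBack"])
        else:
            foot = ankle + np.array([sgn * _SEGMENTS["foot"], 0.0])
            heel = ankle - np.array([sgn * _SEGMENTS["heel"], 0.0])
        # arm chain: upper arm hangs at a small fixed splay; the wrist
        # realizes the elbow angle
        hang = np.tile([np.sin(sgn * 0.15), -np.cos(sgn * 0.15)], (T, 1))
        elbow = shoulder + _SEGMENTS["upper_arm"] * hang
        u_es = (shoulder - elbow) / np.linalg.norm(shoulder - elbow, axis=1, keepdims=True)
        wrist = elbow + _SEGMENTS["forearm"] * _rot(u_es, sgn * rad[f"{S}Elbow"])
        coords.update({
            f"{side}_shoulder": shoulder, f"{side}_elbow": elbow,
            f"{side}_wrist": wrist, f"{side}_hip": hip, f"{side}_knee": knee,
            f"{side}_ankle": ankle, f"{side}_heel": heel, f"{side}_foot_index": foot,
        })
    stack = np.stack([coords[n] for n in CANONICAL16_NAMES], axis=1)  # (T, 16, 2)
    if jitter_sd > 0:
        stack = stack + np.random.default_rng(seed).normal(0.0, jitter_sd, stack.shape)
    return PoseSequence(
        subject_id=angles.subject_id,
        view=angles.view,
        dialect="canonical16",
        joint_names=list(CANONICAL16_NAMES),
        coords=stack,
        frame_index=np.asarray(angles.frame_index),
        visibility=np.ones((T, 16)),
    )


def simulate_pose_sequence(
    params: GaitModelParams,
    view: str,
    seed: int = 0,
    sequence_role: Literal["reference", "target"] = "reference",
    n_frames: int = 100,
    noise_sd: float = 0.0,
    jitter_sd: float = 0.0,
) -> PoseSequence:
    """Simulated angles embedded as a canonical-16 landmark sequence."""
    angles = simulate_angle_series(
        params, view, sequence_role=sequence_role, seed=seed,
        n_frames=n_frames, noise_sd=noise_sd,
    )
    return embed_angles_as_pose(angles, jitter_sd=jitter_sd, seed=seed + 1)


def _spawned_seed(root: np.random.SeedSequence, *key: int) -> int:
    # stable per-(subject, view, role) substream below 2**31
    return int(np.random.SeedSequence(entropy=root.entropy, spawn_key=key)
               .generate_state(1)[0] % (2**31))


def make_angle_dataset(config: CohortConfig, seed: int):
    """Reference and target angle datasets for a whole cohort.

    Returns ``(references, targets)``, each ``identity -> view ->
    JointAngleSeries``, with independent noise per (subject, view, role)
    and bit-identical output for identical (config, seed).
    """
    root = np.random.SeedSequence(seed)
    subjects = sample_cohort(config, _spawned_seed(root, 0))
    references: dict = {}
    targets: dict = {}
    for si, params in enumerate(subjects):
        references[params.subject_id] = {}
        targets[params.subject_id] = {}
        for vi, view in enumerate(config.views):
            for role, store, rk in (("reference", references, 1), ("target", targets, 2)):
                store[params.subject_id][view] = simulate_angle_series(
                    params, view, sequence_role=role,
                    seed=_spawned_seed(root, rk, si, vi),
                    n_frames=config.n_frames, noise_sd=config.view_noise_sd,
                )
    return references, targets


def make_pose_dataset(config: CohortConfig, seed: int):
    """Like :func:`make_angle_dataset` but yielding PoseSequences."""
    root = np.random.SeedSequence(seed)
    subjects = sample_cohort(config, _spawned_seed(root, 0))
    references: dict = {}
    targets: dict = {}
    for si, params in enumerate(subjects):
        references[params.subject_id] = {}
        targets[params.subject_id] = {}
        for vi, view in enumerate(config.views):
            for role, store, rk in (("reference", references, 1), ("target", targets, 2)):
                store[params.subject_id][view] = simulate_pose_sequence(
                    params, view, sequence_role=role,
                    seed=_spawned_seed(root, rk, si, vi),
                    n_frames=config.n_frames, noise_sd=config.view_noise_sd,
                    jitter_sd=config.landmark_jitter_sd,
                )
    return references, targets
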