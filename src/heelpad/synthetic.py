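"""Synthetic gait cohorts for the heel-pad pipeline.

The study data this package analyzes (dual-fluoroscopy thickness plus
pressure-plate force during barefoot gait at ~1 m/s) are not publicly
deposited, so this module generates cohorts with the reported statistical
structure and pushes them through the forward Kelvin-Voigt model:

* per-subject covariates (age 23-72 y, BMI ~24.6 kg/m^2) and per-heel
  material parameters sampled from a latent Gaussian regression calibrated
  to the reported medians and correlation signs (age vs. thickness
  negative, age vs. viscous modulus positive, elastic vs. viscous modulus
  strongly positive);
* a raised-cosine stance-phase compression trajectory (single
  loading/unloading cycle, loading fraction 0.45 of stance by default);
* stress from sigma = E*eps + eta*eps*epsdot with optional multiplicative
  measurement noise, thickness h0*(1-eps), force = stress * heel area;
* post-loading condition obtained from the time-zero heel by multiplying
  the viscous modulus by 20.37/43.9 and the unloaded thickness by
  15.72/15.99 (the two effects reported as significant); elastic modulus
  and peak strain carry over unchanged (reported non-significant).

The stress channel is generated with the same finite-difference strain
rate the analysis uses, so a noiseless simulate/analyze round trip
recovers (E, eta) to numerical precision.

All randomness flows from one integer seed; each heel draws from a
substream derived deterministically from (seed, subject, side, condition).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTrajectoryError, InvalidConfigError
from .geometry import GeometryScene
from .mechanics import KPA_PER_N_CM2, TrialTimeSeries, strain_rate

__all__ = [
    "HeelParams",
    "GaitConfig",
    "CohortConfig",
    "sample_cohort",
    "simulate_stance",
    "render_scene",
    "simulate_cohort",
]

SIDES = ("left", "right")
CONDITIONS = ("time_zero", "post_loading")


@dataclass(frozen=True)
class HeelParams:
    """Ground-truth parameters of one heel in one loading condition."""

    subject_id: str
    side: str  # left | right
    condition: str  # time_zero | post_loading
    age: float  # years
    bmi: float  # kg/m^2
    h0_true: float  # mm, unloaded pad thickness
    E_true: float  # kPa
    eta_true: float  # kPa*s
    peak_strain_true: float  # dimensionless, in (0, 1)
    stance_duration: float = 0.6  # s
    noise_cv: float = 0.01  # multiplicative stress-noise CV

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.h0_true <= 0:
            raise ValueError("h0_true must be positive")
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if self.eta_true < 0:
            raise ValueError("eta_true must be non-negative")
        if not 0.0 < self.peak_strain_true < 1.0:
            raise ValueError("peak_strain_true must lie in (0, 1)")
        if self.stance_duration <= 0:
            raise ValueError("stance_duration must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class GaitConfig:
    """Sampling and scene-rendering knobs shared across a cohort.

    The 50 Hz frame rate matches the fluoroscope acquisition; gait velocity
    is documentation only (the trajectory is parameterised by stance
    duration, not speed). ``heel_area_cm2`` is the scalar heel contact area
    used to convert stress to plate force. ``thickness_noise_sd`` adds
    optional Gaussian noise (mm) to the thickness channel — off by default;
    0.05 mm is a typical value when emulating fluoroscopic measurement
    error.
    """

    frame_rate: float = 50.0  # Hz
    gait_velocity: float = 1.0  # m/s, documentation only
    trajectory_shape: str = "asymmetric_cosine"  # or "raised_cosine"
    loading_fraction: float = 0.45  # fraction of stance spent loading
    contact_force_threshold: float = 10.0  # N
    heel_area_cm2: float = 25.0
    ball_radius: float = 5.0  # mm
    n_cloud_points: int = 200
    plate_tilt_deg: float = 0.0
    thickness_noise_sd: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidConfigError("frame_rate must be positive")
        if self.n_cloud_points < 1:
            raise InvalidConfigError("n_cloud_points must be >= 1")
        if not 0.0 < self.loading_fraction < 1.0:
            raise InvalidConfigError("loading_fraction must lie in (0, 1)")
        if self.trajectory_shape not in ("raised_cosine", "asymmetric_cosine"):
            raise InvalidConfigError(
                f"unknown trajectory_shape {self.trajectory_shape!r}"
            )
        if self.heel_area_cm2 <= 0:
            raise InvalidConfigError("heel_area_cm2 must be positive")
        if self.ball_radius <= 0:
            raise InvalidConfigError("ball_radius must be positive")
        if self.thickness_noise_sd < 0:
            raise InvalidConfigError("thickness_noise_sd must be >= 0")


@dataclass
class CohortConfig:
    """Population model of the synthetic cohort.

    Defaults are calibrated to the study cohort: 10 subjects aged 23-72,
    BMI 24.6 +/- 3.5 kg/m^2, per-condition medians h0 15.99/15.72 mm,
    eta 43.9/20.37 kPa*s, E 192.55 kPa and peak strain 0.685 (E and peak
    strain unchanged post-loading; their observed post medians, 197.585 kPa
    and 0.69, were not significantly different). Correlation knobs set the
    population Pearson R between age and thickness (-0.507), age and
    viscous modulus (+0.518), elastic and viscous moduli (+0.821), and
    elastic modulus and peak strain (-0.765). ``side_cv`` is the small
    multiplicative left/right variation around the subject value.
    """

    n_subjects: int = 10
    age_range: tuple[float, float] = (23.0, 72.0)
    bmi_mean: float = 24.6
    bmi_sd: float = 3.5
    h0_median: float = 15.99  # mm, time zero
    h0_sd: float = 1.8
    E_median: float = 192.55  # kPa
    E_sd: float = 30.0
    eta_median: float = 43.9  # kPa*s, time zero
    eta_sd: float = 13.0
    peak_strain_median: float = 0.685
    peak_strain_sd: float = 0.02
    r_age_h0: float = -0.507
    r_age_eta: float = 0.518
    r_E_eta: float = 0.821
    r_E_strain: float = -0.765
    side_cv: float = 0.02
    eta_post_multiplier: float = 20.37 / 43.9
    h0_post_multiplier: float = 15.72 / 15.99
    stance_duration: float = 0.6  # s
    noise_cv: float = 0.01
    eta_floor: float = 2.0  # kPa*s, guards rare negative tail draws

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise InvalidConfigError("n_subjects must be >= 0")
        for name in ("h0_sd", "E_sd", "eta_sd", "peak_strain_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise InvalidConfigError("age_range must be (low, high) with low < high")
        for name in ("r_age_h0", "r_age_eta", "r_E_eta", "r_E_strain"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise InvalidConfigError(f"{name} must lie in (-1, 1)")
        if self.r_age_eta**2 + self.r_E_eta**2 >= 1.0:
            raise InvalidConfigError(
                "r_age_eta^2 + r_E_eta^2 must be < 1 for a valid latent model"
            )
        if self.side_cv < 0 or self.noise_cv < 0:
            raise InvalidConfigError("side_cv and noise_cv must be >= 0")
        for name in ("eta_post_multiplier", "h0_post_multiplier"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")


def _heel_rng(seed: int, subject_id: str, side: str, condition: str, salt: int = 0):
    """Deterministic per-heel substream from (seed, subject, side, condition)."""
    return np.random.default_rng(
        [
            int(seed),
            zlib.crc32(subject_id.encode()),
            SIDES.index(side),
            CONDITIONS.index(condition),
            salt,
        ]
    )


def sample_cohort(cfg: CohortConfig, seed: int) -> list[HeelParams]:
    """Sample 2 sides x 2 conditions = 4 :class:`HeelParams` per subject.

    Subject-level values come from a latent Gaussian regression on
    standardized age (uniform over the configured range): thickness and the
    viscous modulus load on age with the configured correlations, the
    viscous modulus additionally on the elastic-modulus latent, and peak
    strain on the elastic-modulus latent. Per-side multiplicative jitter
    (``side_cv``) then splits left from right; the post-loading condition
    applies the eta/h0 multipliers to the same heel value, so condition
    contrasts are paired by construction.
    """
    rng = np.random.default_rng([int(seed)])
    lo, hi = cfg.age_range
    age_sd = (hi - lo) / np.sqrt(12.0)
    g_eta = np.sqrt(1.0 - cfg.r_age_eta**2 - cfg.r_E_eta**2)
    out: list[HeelParams] = []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:03d}"
        age = float(rng.uniform(lo, hi))
        z_age = (age - (lo + hi) / 2.0) / age_sd
        bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 15.0, 45.0))
        u_E, u_eta, u_h, u_s = rng.standard_normal(4)
        h0 = cfg.h0_median + cfg.h0_sd * (
            cfg.r_age_h0 * z_age + np.sqrt(1.0 - cfg.r_age_h0**2) * u_h
        )
        E = cfg.E_median + cfg.E_sd * u_E
        eta = cfg.eta_median + cfg.eta_sd * (
            cfg.r_age_eta * z_age + cfg.r_E_eta * u_E + g_eta * u_eta
        )
        strain = cfg.peak_strain_median + cfg.peak_strain_sd * (
            cfg.r_E_strain * u_E + np.sqrt(1.0 - cfg.r_E_strain**2) * u_s
        )
        h0 = max(h0, 3.0)
        E = max(E, 10.0)
        eta = max(eta, cfg.eta_floor)
        strain = float(np.clip(strain, 0.05, 0.95))
        for side in SIDES:
            jit = 1.0 + cfg.side_cv * rng.standard_normal(4)
            jit = np.clip(jit, 0.5, 1.5)
            h0_s, E_s, eta_s, strain_s = (
                h0 * jit[0],
                E * jit[1],
                eta * jit[2],
                float(np.clip(strain * jit[3], 0.05, 0.95)),
            )
            for condition in CONDITIONS:
                post = condition == "post_loading"
                out.append(
                    HeelParams(
                        subject_id=sid,
                        side=side,
                        condition=condition,
                        age=age,
                        bmi=bmi,
                        h0_true=h0_s * (cfg.h0_post_multiplier if post else 1.0),
                        E_true=E_s,
                        eta_true=eta_s * (cfg.eta_post_multiplier if post else 1.0),
                        peak_strain_true=strain_s,
                        stance_duration=cfg.stance_duration,
                        noise_cv=cfg.noise_cv,
                    )
                )
    return out


def _strain_trajectory(
    t: np.ndarray, duration: float, peak: float, loading_fraction: float
) -> np.ndarray:
    """Raised-cosine up/down: 0 -> peak over the loading fraction, back to 0."""
    t_load = loading_fraction * duration
    eps = np.empty_like(t)
    up = t <= t_load
    eps[up] = 0.5 * peak * (1.0 - np.cos(np.pi * t[up] / t_load))
    eps[~up] = 0.5 * peak * (
        1.0 + np.cos(np.pi * (t[~up] - t_load) / (duration - t_load))
    )
    return eps


def simulate_stance(p: HeelParams, g: GaitConfig, seed: int) -> TrialTimeSeries:
    """Forward-simulate one stance-phase trial for one heel.

    Frames are sampled at 1/frame_rate over the stance duration (inclusive
    endpoints). The noiseless stress channel is exactly
    ``E_true*eps + eta_true*eps*epsdot`` with ``epsdot`` the same
    central-finite-difference tangent the analysis computes; multiplicative
    Gaussian noise of CV ``noise_cv`` is applied when positive. Thickness is
    ``h0_true*(1 - eps)`` (plus optional additive noise); force is stress
    times the configured heel area. The touch-down frame (0) is recorded as
    ``contact_index``.
    """
    n = int(round(p.stance_duration * g.frame_rate)) + 1
    if n < 3:
        raise DegenerateTrajectoryError(
            f"stance of {p.stance_duration} s at {g.frame_rate} Hz gives "
            f"{n} frame(s); need >= 3"
        )
    t = np.arange(n) / g.frame_rate
    frac = 0.5 if g.trajectory_shape == "raised_cosine" else g.loading_fraction
    eps = _strain_trajectory(t, p.stance_duration, p.peak_strain_true, frac)
    epsdot = strain_rate(eps, t)
    sigma = p.E_true * eps + p.eta_true * eps * epsdot
    rng = _heel_rng(seed, p.subject_id, p.side, p.condition)
    if p.noise_cv > 0:
        sigma = sigma * (1.0 + p.noise_cv * rng.standard_normal(n))
    thickness = p.h0_true * (1.0 - eps)
    if g.thickness_noise_sd > 0:
        thickness = thickness + g.thickness_noise_sd * rng.standard_normal(n)
    force = sigma * g.heel_area_cm2 / KPA_PER_N_CM2
    return TrialTimeSeries(
        time=t,
        thickness=thickness,
        force=force,
        area=np.full(n, g.heel_area_cm2),
        contact_index=0,
        meta={
            "subject_id": p.subject_id,
            "side": p.side,
            "condition": p.condition,
        },
    )


def _rotation_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def render_scene(
    p: HeelParams, ts: TrialTimeSeries, g: GaitConfig, seed: int
) -> GeometryScene:
    """Render a 3D marker-ball + calcaneus-cloud scene matching a trial.

    Three non-collinear ball centers sit one radius above the plate plane.
    The calcaneus is a rigid lower-half ellipsoid shell of
    ``n_cloud_points`` (semi-axes 25 x 18 x 20 mm), translated vertically
    per frame so the minimum cloud-to-plate distance equals the trial's
    thickness channel exactly. An optional plate tilt rotates balls and
    cloud rigidly together, leaving the recovered thickness invariant.
    """
    rng = _heel_rng(seed, p.subject_id, p.side, p.condition, salt=101)
    centers = np.array(
        [
            [0.0, 0.0, g.ball_radius],
            [120.0, 0.0, g.ball_radius],
            [0.0, 100.0, g.ball_radius],
        ]
    )
    # rigid calcaneus shell: lower hemisphere of an ellipsoid
    v = rng.standard_normal((g.n_cloud_points, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 2] = -np.abs(v[:, 2])
    shell = v * np.array([25.0, 18.0, 20.0])
    shell[:, 0] += 40.0
    shell[:, 1] += 35.0
    z_min = shell[:, 2].min()
    rot = _rotation_x(g.plate_tilt_deg) if g.plate_tilt_deg else None
    frames = []
    for time, h in zip(ts.time, ts.thickness):
        cloud = shell.copy()
        cloud[:, 2] = h + (shell[:, 2] - z_min)  # lowest point at height h, exact
        if rot is not None:
            cloud = cloud @ rot.T
        frames.append((float(time), cloud))
    if rot is not None:
        centers = centers @ rot.T
    return GeometryScene(
        ball_centers=centers,
        ball_radius=g.ball_radius,
        frames=frames,
        plate_tilt_deg=g.plate_tilt_deg,
    )


def simulate_cohort(
    cfg: CohortConfig, gait: GaitConfig, seed: int
) -> list[tuple[HeelParams, TrialTimeSeries]]:
    """Sample a cohort and simulate one trial per heel (convenience wrapper)."""
    return [
        (p, simulate_stance(p, gait, seed)) for p in sample_cohort(cfg, seed)
    ]
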