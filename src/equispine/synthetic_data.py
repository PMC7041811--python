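"""Synthetic trot motion and synthetic study datasets with known truth.

Two generators make every pipeline stage testable without recorded data:

* :func:`simulate_trot_markers` builds marker trajectories for a parametric
  horse advected along a straight line or a lunge circle.  The generator is
  kinematic — angle waveforms are *prescribed*, not emergent — so every
  quantity the pipeline estimates has an exact ground truth in the config.
  The trot's phase structure is respected: vertical displacement of head,
  withers and sacrum and back flexion-extension (including pelvic pitch)
  oscillate at twice the stride frequency; lateral bending, axial rotation
  (pelvic roll) and pelvic yaw complete one cycle per stride.

* :func:`simulate_measurement_dataset` emulates a full repeated-measures
  study: measurement means for several horses over three days (5 + 5 + 2
  measurements) and four path-surface conditions, with a horse-level random
  effect, heteroscedastic day/repetition effects on the residual scale and
  known variance components.

Default magnitudes are seeded from typical over-ground trot values (e.g. a
0.75 s stride, ~3.8 m/s on the soft straight, pelvic roll ROM near 10
degrees), so synthetic output is magnitude-realistic.  Fixed seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_markers import (
    CONDITIONS,
    MARKER_ROLES,
    MarkerConfig,
    MarkerFrameSeries,
    condition_label,
)

__all__ = [
    "TrotSimConfig",
    "StudySimConfig",
    "simulate_trot_markers",
    "simulate_measurement_dataset",
    "true_icc",
]

_GRAVITY_MM_S2 = 9810.0

#: Local body geometry (mm): x cranial, y left, z up, origin at the ground
#: point below the tuber sacrale.  The T15 marker sits midway along the
#: withers–tuber sacrale chord so a chord-perpendicular apex displacement h
#: produces a whole-back angle of exactly 2*atan(h / 500).
_SPINE_X = {
    "withers_mid": 1000.0,
    "T12": 750.0,
    "T15": 500.0,
    "T18": 350.0,
    "L3": 200.0,
    "L5": 100.0,
    "tuber_sacrale": 0.0,
    "S5": -80.0,
}
_BACK_Z = 1400.0
_WITHERS_LAT = 200.0   # lateral withers markers: 20 cm off the midline
_NECK_LEN = 900.0
_HEAD_Z = 1600.0
_PELVIS_DX = 150.0     # tuber sacrale -> inter-coxae midpoint, cranial
_PELVIS_DZ = -100.0    # ... and ventral
_PELVIS_HALFSPAN = 260.0
_HALF_CHORD = 500.0    # withers–T15 and T15–tuber sacrale half chord


def _bump(x: float) -> float:
    """Back-bending mode shape: 1 at T15, 0 at withers and tuber sacrale."""
    return max(0.0, 1.0 - ((x - 500.0) / 500.0) ** 2)


@dataclass(frozen=True)
class TrotSimConfig:
    """Ground truth for the marker simulator.

    Amplitudes are half-ranges: a parameter driven with amplitude ``A``
    yields a per-stride range of motion of ``2 A``.  ``body_lean_deg=None``
    selects no lean on the straight and the physical bank angle
    ``atan(v^2 / (g r))`` (leaning into the turn) on the circle.
    """

    stride_frequency: float = 4.0 / 3.0          # Hz (0.75 s stride)
    speed: float = 3.79                          # m/s
    path: str = "straight"                       # straight | circle
    circle_radius: float = 4.85                  # m
    circle_direction: str = "left"               # left | right
    n_strides: int = 14
    sampling_rate: float = 100.0                 # Hz
    amp_flex_ext: float = 2.49                   # deg, whole-back flex-ext
    amp_lat_bend: float = 3.72                   # deg, whole-back lat bend
    amp_pelvis_roll: float = 4.83                # deg
    amp_pelvis_pitch: float = 3.81               # deg
    amp_pelvis_yaw: float = 2.15                 # deg
    head_swivel_offset: float = -1.28            # deg, mean cervical bend
    amp_head_swivel: float = 3.0                 # deg
    body_tracking_offset: float = 0.0            # deg
    amp_head_z: float = 35.4                     # mm
    amp_withers_z: float = 46.8                  # mm
    amp_sacrum_z: float = 48.2                   # mm
    body_lean_deg: float | None = None
    noise_sd_mm: float = 3.2                     # per-axis marker noise
    marker_offsets: Mapping[str, tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stride_frequency", "sampling_rate", "amp_flex_ext",
                     "amp_lat_bend", "amp_pelvis_roll", "amp_pelvis_pitch",
                     "amp_pelvis_yaw", "amp_head_swivel", "amp_head_z",
                     "amp_withers_z", "amp_sacrum_z", "noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stride_frequency == 0 or self.sampling_rate == 0:
            raise ValueError("frequencies must be positive")
        if self.path not in ("straight", "circle"):
            raise ValueError("path must be 'straight' or 'circle'")
        if self.circle_radius <= 0:
            raise ValueError("circle_radius must be > 0")
        if self.circle_direction not in ("left", "right"):
            raise ValueError("circle_direction must be 'left' or 'right'")

    @property
    def lean_deg(self) -> float:
        """Effective body lean (deg, positive = right side down)."""
        if self.body_lean_deg is not None:
            return float(self.body_lean_deg)
        if self.path == "straight":
            return 0.0
        bank = np.rad2deg(np.arctan(
            (self.speed * 1000.0) ** 2
            / (_GRAVITY_MM_S2 * self.circle_radius * 1000.0)))
        # Leaning into the turn: top toward the circle centre.
        return -bank if self.circle_direction == "left" else bank


def simulate_trot_markers(config: TrotSimConfig) -> MarkerFrameSeries:
    """Marker trajectories for one simulated trot-up.

    Labels equal the role names, so :meth:`MarkerConfig.identity` reads the
    output directly.  The trial spans ``n_strides + 1`` stride periods; the
    stride-segmentation phase convention (sacrum minima at which pelvic roll
    is increasing) yields exactly ``n_strides`` complete strides.
    """
    cfg = config
    f = cfg.stride_frequency
    rate = cfg.sampling_rate
    duration = (cfg.n_strides + 1) / f
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    # Phase origin 0.3 strides in, keeping boundary minima off the edges.
    tau = t - 0.3 / f
    w1 = 2.0 * np.pi * f * tau          # once-per-stride phase
    w2 = 4.0 * np.pi * f * tau          # twice-per-stride phase

    theta_fe = np.deg2rad(cfg.amp_flex_ext) * np.sin(w2)
    theta_lb = np.deg2rad(cfg.amp_lat_bend) * np.sin(w1 + np.pi / 3)
    roll = np.deg2rad(cfg.amp_pelvis_roll) * np.sin(w1)
    pitch_base = np.arctan2(_PELVIS_DZ, _PELVIS_DX)
    pitch = pitch_base + np.deg2rad(cfg.amp_pelvis_pitch) * np.sin(w2 + np.pi / 4)
    yaw = np.deg2rad(cfg.amp_pelvis_yaw) * np.sin(w1 + 2 * np.pi / 3)
    swivel = np.deg2rad(cfg.head_swivel_offset
                        + cfg.amp_head_swivel * np.sin(w1 + np.pi / 5))

    osc = -np.cos(w2)                   # shared vertical phase, minima on grid
    h_fe = _HALF_CHORD * np.tan(theta_fe / 2.0)
    h_lb = _HALF_CHORD * np.tan(theta_lb / 2.0)

    local: dict[str, np.ndarray] = {}
    amp_z = {"withers_mid": cfg.amp_withers_z, "tuber_sacrale": cfg.amp_sacrum_z}

    def spine_amp(x: float) -> float:
        # vertical amplitude interpolated withers -> sacrum along the back
        frac = np.clip(x / _SPINE_X["withers_mid"], 0.0, 1.0)
        return cfg.amp_sacrum_z + (cfg.amp_withers_z - cfg.amp_sacrum_z) * frac

    for role, x in _SPINE_X.items():
        b = _bump(x)
        pos = np.empty((n, 3))
        pos[:, 0] = x
        pos[:, 1] = h_lb * b
        pos[:, 2] = _BACK_Z + spine_amp(x) * osc - h_fe * b
        local[role] = pos

    for role, side in (("withers_left", 1.0), ("withers_right", -1.0)):
        pos = local["withers_mid"].copy()
        pos[:, 1] += side * _WITHERS_LAT
        pos[:, 2] -= 20.0
        local[role] = pos

    # Pelvic triad: construct the tuber coxae line so the projected roll,
    # pitch and yaw equal the prescribed waveforms exactly.
    ts = local["tuber_sacrale"]
    lp = np.hypot(_PELVIS_DX, _PELVIS_DZ)
    mid = ts + np.column_stack([lp * np.cos(pitch), np.zeros(n), lp * np.sin(pitch)])
    d = np.column_stack([np.tan(yaw), -np.ones(n), -np.tan(roll)])
    local["tuber_coxae_left"] = mid - _PELVIS_HALFSPAN * d
    local["tuber_coxae_right"] = mid + _PELVIS_HALFSPAN * d

    head = local["withers_mid"].copy()
    head[:, 0] += _NECK_LEN * np.cos(swivel)
    head[:, 1] += -_NECK_LEN * np.sin(swivel)
    head[:, 2] = _HEAD_Z + cfg.amp_head_z * osc
    local["head_ref"] = head

    if cfg.marker_offsets:
        for role, off in cfg.marker_offsets.items():
            local[role] = local[role] + np.asarray(off, float)

    # Body lean: right-hand rotation about the local x axis at ground level.
    lam = np.deg2rad(cfg.lean_deg)
    if lam != 0.0:
        c, s = np.cos(lam), np.sin(lam)
        for role, pos in local.items():
            y, z = pos[:, 1].copy(), pos[:, 2].copy()
            pos[:, 1] = c * y - s * z
            pos[:, 2] = s * y + c * z

    # Path placement: heading psi(t), body yawed right of travel by the
    # body-tracking offset (a +z rotation turns the nose left).
    v_mm = cfg.speed * 1000.0
    if cfg.path == "straight":
        px, py = v_mm * t, np.zeros(n)
        psi = np.zeros(n)
    else:
        r_mm = cfg.circle_radius * 1000.0
        omega = v_mm / r_mm
        if cfg.circle_direction == "left":
            phi = omega * t
            psi = phi + np.pi / 2
        else:
            phi = -omega * t
            psi = phi - np.pi / 2
        px, py = r_mm * np.cos(phi), r_mm * np.sin(phi)
    body_yaw = psi - np.deg2rad(cfg.body_tracking_offset)

    rng = np.random.default_rng(cfg.seed)
    cb, sb = np.cos(body_yaw), np.sin(body_yaw)
    positions: dict[str, np.ndarray] = {}
    for role in MARKER_ROLES:
        pos = local[role]
        world = np.empty_like(pos)
        world[:, 0] = cb * pos[:, 0] - sb * pos[:, 1] + px
        world[:, 1] = sb * pos[:, 0] + cb * pos[:, 1] + py
        world[:, 2] = pos[:, 2]
        if cfg.noise_sd_mm > 0:
            world = world + rng.normal(0.0, cfg.noise_sd_mm, world.shape)
        positions[role] = world
    return MarkerFrameSeries(sampling_rate=rate, positions=positions)


# ---------------------------------------------------------------------------
# Study-level simulator
# ---------------------------------------------------------------------------

#: Condition means seeded from typical over-ground trot medians (deg, m/s).
_DEFAULT_MEANS: dict[str, dict[str, float]] = {
    "back_flex_ext": {"hard_straight": 4.91, "soft_straight": 4.97,
                      "soft_left": 5.71, "soft_right": 5.55},
    "back_lat_bend": {"hard_straight": 6.46, "soft_straight": 7.45,
                      "soft_left": 7.80, "soft_right": 7.77},
    "pelvis_roll": {"hard_straight": 8.51, "soft_straight": 9.65,
                    "soft_left": 8.77, "soft_right": 9.35},
    "pelvis_pitch": {"hard_straight": 6.98, "soft_straight": 7.62,
                     "soft_left": 8.08, "soft_right": 8.27},
    "pelvis_yaw": {"hard_straight": 3.95, "soft_straight": 4.29,
                   "soft_left": 5.23, "soft_right": 5.26},
    "speed": {"hard_straight": 3.35, "soft_straight": 3.79,
              "soft_left": 3.30, "soft_right": 3.35},
}

#: Residual SDs sized so 95 % between-measurement prediction limits land
#: near 1 degree (0.2 m/s for speed); horse SDs twice that (ICC = 0.8).
_DEFAULT_SIGMA_RESID = {
    "back_flex_ext": 0.40, "back_lat_bend": 0.50, "pelvis_roll": 0.65,
    "pelvis_pitch": 0.50, "pelvis_yaw": 0.35, "speed": 0.20,
}

_DAY_OF_MEASUREMENT = {m: ("day1" if m <= 5 else "day2" if m <= 10 else "recheck")
                       for m in range(1, 13)}


@dataclass(frozen=True)
class StudySimConfig:
    """Ground truth for the measurement-mean dataset simulator.

    ``value = mean[param][condition] + horse_effect + resid`` with
    ``horse_effect ~ N(0, sigma_horse^2)`` and ``resid ~ N(0, (sigma_resid *
    m)^2)`` where the multiplier ``m = day_var_factors[day] * max(0.1, 1 +
    rep_var_slope * (rep_index - 1))`` makes repeated measurements more
    variable at the recheck and (slightly) less variable over within-day
    repetitions — the dispersion effects the variability model is built to
    detect.  Defaults: 12 horses, 5 + 5 + 2 measurements over three days,
    four conditions, three horses missing the recheck.
    """

    n_horses: int = 12
    means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MEANS.items()})
    sigma_horse: Mapping[str, float] = field(
        default_factory=lambda: {k: 2.0 * v for k, v in _DEFAULT_SIGMA_RESID.items()})
    sigma_resid: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SIGMA_RESID))
    day_var_factors: Mapping[str, float] = field(
        default_factory=lambda: {"day1": 1.0, "day2": 1.0, "recheck": 1.5})
    rep_var_slope: float = -0.05
    n_missing_recheck: int = 3
    n_strides_straight: float = 14.0
    n_strides_lunge: float = 36.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_horses < 2:
            raise ValueError("need at least 2 horses")
        for k, v in self.sigma_horse.items():
            if v < 0:
                raise ValueError(f"sigma_horse[{k!r}] must be >= 0")
        for k, v in self.sigma_resid.items():
            if v < 0:
                raise ValueError(f"sigma_resid[{k!r}] must be >= 0")


def true_icc(config: StudySimConfig, parameter: str) -> float:
    """Closed-form ICC implied by the config (homoscedastic settings)."""
    vh = config.sigma_horse[parameter] ** 2
    vr = config.sigma_resid[parameter] ** 2
    if vh + vr == 0:
        return 1.0
    return vh / (vh + vr)


def simulate_measurement_dataset(config: StudySimConfig) -> pd.DataFrame:
    """One synthetic measurement-mean table (wide, one row per trot-up)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    params = list(cfg.means)
    horses = [f"H{h + 1:02d}" for h in range(cfg.n_horses)]
    missing = set(horses[:cfg.n_missing_recheck])

    horse_eff = {p: dict(zip(horses,
                             rng.normal(0.0, cfg.sigma_horse[p], cfg.n_horses)))
                 for p in params}

    conditions = [("straight", "hard"), ("straight", "soft"),
                  ("lunge_left", "soft"), ("lunge_right", "soft")]
    rows = []
    for horse in horses:
        for m in range(1, 13):
            day = _DAY_OF_MEASUREMENT[m]
            if day == "recheck" and horse in missing:
                continue
            rep = (m - 1) % 5 + 1 if m <= 10 else m - 10
            mult = cfg.day_var_factors.get(day, 1.0) * max(
                0.1, 1.0 + cfg.rep_var_slope * (rep - 1))
            for path, surface in conditions:
                cond = condition_label(path, surface)
                base_n = (cfg.n_strides_straight if path == "straight"
                          else cfg.n_strides_lunge)
                row = {
                    "horse": horse, "day": day, "measurement_no": m,
                    "path": path, "surface": surface,
                    "n_strides": int(max(6, round(rng.normal(base_n, 2.0)))),
                }
                for p in params:
                    row[p] = (cfg.means[p][cond] + horse_eff[p][horse]
                              + rng.normal(0.0, cfg.sigma_resid[p] * mult))
                row["condition"] = cond
                rows.append(row)
    return pd.DataFrame(rows)
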