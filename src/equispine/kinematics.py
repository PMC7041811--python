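"""Kinematic parameters of the trotting horse from marker trajectories.

The measurement chain implemented here:

1. zero-phase low-pass filtering of all marker coordinates (4th-order
   Butterworth, 30 Hz cut-off by default);
2. a per-frame *horse frame* built from the smoothed velocity of the tuber
   sacrale marker: x-hat = horizontal direction of travel, z-hat = up,
   y-hat = z-hat x x-hat (pointing left).  Using the heading rather than a
   lab axis makes straight lines and circles uniform;
3. optional *lean correction*: on the circle the horse leans into the turn,
   so the sagittal/dorsal/frontal planes are rotated about the direction of
   travel by the body lean angle (stride-mean pelvic roll) before angles are
   projected;
4. all back/pelvic angles as signed projection angles in those planes.

Angle sign conventions (right-handed, x-hat forward, z-hat up):

* pelvic roll: positive when the right tuber coxae drops (right-hand
  rotation about x-hat);
* pelvic pitch: inclination of tuber sacrale -> inter-coxae midpoint in the
  sagittal plane, positive upward;
* pelvic yaw: positive when the pelvis line turns nose-left (right-hand
  rotation about z-hat);
* back angles: deviation from collinearity, positive when the apex marker
  lies below (sagittal) / left of (dorsal) the cranial-caudal chord;
* body tracking: positive = forehand tracking to the right of travel;
* head swivel: positive = cervical bending to the right.

Angles are reported in degrees; vertical displacements in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io_markers import MarkerConfig, MarkerFrameSeries

__all__ = [
    "DegenerateGeometryError",
    "FilterParameterError",
    "HorseFrame",
    "AngleSeries",
    "lowpass_filter",
    "heading_frame",
    "lean_correct",
    "projection_angle",
    "pelvic_angles",
    "back_angle",
    "body_tracking_angle",
    "head_swivel_angle",
    "speed_from_marker",
    "BACK_ANGLE_MARKERS",
    "PARAMETER_UNITS",
    "compute_angles",
]


class DegenerateGeometryError(ValueError):
    """A vector to be projected vanishes in the requested plane."""


class FilterParameterError(ValueError):
    """Invalid filter parameters (e.g. cut-off at or above Nyquist)."""


# ---------------------------------------------------------------------------
# Filtering and smoothed differentiation
# ---------------------------------------------------------------------------


def lowpass_filter(
    x: np.ndarray,
    cutoff_hz: float,
    sampling_rate: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter along axis 0.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth magnitude and the
    phase is zero — stride timing is not shifted.
    """
    x = np.asarray(x, dtype=float)
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise FilterParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate,
                        output="sos")
    padlen = min(x.shape[0] - 1, 3 * (2 * sos.shape[0] + 1))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def _odd_window(n_frames: int, sampling_rate: float, window_s: float) -> int:
    w = int(round(window_s * sampling_rate))
    w = max(w, 3)
    if w % 2 == 0:
        w += 1
    if w > n_frames:
        w = n_frames if n_frames % 2 == 1 else n_frames - 1
    return max(w, 3)


def smoothed_derivative(
    x: np.ndarray,
    sampling_rate: float,
    window_s: float = 0.5,
) -> np.ndarray:
    """Moving-regression slope (Savitzky-Golay, polyorder 1, deriv 1).

    A 0.5 s window suppresses the within-stride oscillation while still
    tracking the turning heading on the lunge circle.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    window = _odd_window(x.shape[0], sampling_rate, window_s)
    return signal.savgol_filter(
        x, window_length=window, polyorder=1, deriv=1,
        delta=1.0 / sampling_rate, axis=0, mode="interp")


# ---------------------------------------------------------------------------
# Horse frame
# ---------------------------------------------------------------------------


@dataclass
class HorseFrame:
    """Per-frame orthonormal axes of the horse-centred coordinate system.

    ``xhat`` is the horizontal unit direction of travel, ``zhat`` is up
    before lean correction, ``yhat = zhat x xhat`` points left.  After
    :func:`lean_correct`, ``yhat``/``zhat`` are rotated about ``xhat`` by the
    recorded body lean angle.
    """

    xhat: np.ndarray  # (n, 3)
    yhat: np.ndarray  # (n, 3)
    zhat: np.ndarray  # (n, 3)
    lean_deg: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lean_deg is None:
            self.lean_deg = np.zeros(len(self.xhat))
        self.lean_deg = np.broadcast_to(
            np.asarray(self.lean_deg, float), (len(self.xhat),)).copy()

    @property
    def n_frames(self) -> int:
        return len(self.xhat)


def heading_frame(
    body_marker_xy: np.ndarray,
    sampling_rate: float,
    window_s: float = 0.5,
    min_speed: float = 100.0,
) -> HorseFrame:
    """Horse frame from the smoothed horizontal velocity of a body marker.

    Parameters
    ----------
    body_marker_xy
        ``(n, 2)`` horizontal track (mm), typically the tuber sacrale.
    min_speed
        Minimum smoothed speed (mm/s) below which the heading is considered
        degenerate (default 100 mm/s = 0.1 m/s).
    """
    xy = np.asarray(body_marker_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("body_marker_xy must have shape (n, 2)")
    vel = smoothed_derivative(xy, sampling_rate, window_s)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if np.any(speed < min_speed):
        raise DegenerateGeometryError(
            "stationary or near-stationary track: heading undefined")
    n = len(xy)
    xhat = np.zeros((n, 3))
    xhat[:, :2] = vel / speed[:, None]
    zhat = np.tile([0.0, 0.0, 1.0], (n, 1))
    yhat = np.cross(zhat, xhat)
    return HorseFrame(xhat=xhat, yhat=yhat, zhat=zhat)


def lean_correct(frame: HorseFrame, lean_deg: float | np.ndarray) -> HorseFrame:
    """Rotate the transverse axes so the frame leans with the horse.

    ``lean_deg`` is the body lean angle — stride-mean pelvic roll during one
    complete stride — positive with the same sign convention as pelvic roll
    (right side down).  The rotation is a right-hand rotation of ``yhat`` and
    ``zhat`` about ``xhat``; pelvic roll recomputed in the corrected frame
    then has (near-)zero stride mean.  ``lean_deg = 0`` is the identity and
    correcting by ``+theta`` then ``-theta`` restores the original frame.
    """
    lean = np.broadcast_to(np.asarray(lean_deg, float), (frame.n_frames,))
    if not np.isfinite(lean).all():
        raise ValueError("lean_deg must be finite")
    rad = np.deg2rad(lean)[:, None]
    c, s = np.cos(rad), np.sin(rad)
    yhat = c * frame.yhat + s * frame.zhat
    zhat = -s * frame.yhat + c * frame.zhat
    return HorseFrame(xhat=frame.xhat.copy(), yhat=yhat, zhat=zhat,
                      lean_deg=frame.lean_deg + lean)


# ---------------------------------------------------------------------------
# Projection angles
# ---------------------------------------------------------------------------

#: Ordered in-plane basis (u, w) per anatomical plane; a positive angle
#: rotates from u toward w.
_PLANE_BASES = {
    "sagittal": ("xhat", "zhat"),
    "dorsal": ("xhat", "yhat"),
    "frontal": ("yhat", "zhat"),
}


def _plane_coords(v: np.ndarray, frame: HorseFrame, plane: str):
    try:
        u_name, w_name = _PLANE_BASES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}") from None
    u = getattr(frame, u_name)
    w = getattr(frame, w_name)
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return np.einsum("ij,ij->i", v, u), np.einsum("ij,ij->i", v, w)


def projection_angle(
    v: np.ndarray,
    frame: HorseFrame,
    plane: str,
    reference: np.ndarray | None = None,
    min_norm: float = 1e-9,
) -> np.ndarray:
    """Signed angle between ``v`` projected onto a plane and a reference axis.

    ``plane`` is one of ``sagittal`` (span of x-hat, z-hat), ``dorsal``
    (x-hat, y-hat) or ``frontal`` (y-hat, z-hat).  The reference defaults to
    the first basis axis of the plane; it must lie in (or is projected onto)
    the same plane.  Angles are in degrees in (-180, 180], positive rotating
    from the first toward the second basis axis.
    """
    a, b = _plane_coords(v, frame, plane)
    norm = np.hypot(a, b)
    scale = np.linalg.norm(np.atleast_2d(v), axis=1)
    if np.any(norm <= min_norm * np.maximum(scale, 1.0)):
        raise DegenerateGeometryError(
            f"vector orthogonal to the {plane} plane: projection degenerate")
    if reference is None:
        ra, rb = np.ones_like(a), np.zeros_like(b)
    else:
        ra, rb = _plane_coords(reference, frame, plane)
        rnorm = np.hypot(ra, rb)
        if np.any(rnorm <= min_norm):
            raise DegenerateGeometryError("reference axis degenerate in plane")
    ang = np.arctan2(ra * b - rb * a, ra * a + rb * b)
    out = np.rad2deg(ang)
    return out if out.size > 1 else out.reshape(-1)


def _signed_angle(au, aw, bu, bw):
    """Signed angle from vector a to vector b given in-plane coordinates."""
    return np.rad2deg(np.arctan2(au * bw - aw * bu, au * bu + aw * bw))


# ---------------------------------------------------------------------------
# Angle series container
# ---------------------------------------------------------------------------


@dataclass
class AngleSeries:
    """One kinematic parameter as a per-frame series.

    ``valid`` marks frames where every source marker was tracked; downstream
    stride statistics drop strides containing invalid frames.
    """

    name: str
    values: np.ndarray
    valid: np.ndarray
    units: str = "deg"
    sign_convention: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have equal shape")


# ---------------------------------------------------------------------------
# Pelvic angles
# ---------------------------------------------------------------------------


def pelvic_angles(
    ts: np.ndarray,
    ltc: np.ndarray,
    rtc: np.ndarray,
    frame: HorseFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pelvic roll, pitch and yaw from the tuber sacrale / tubera coxae triad.

    roll  — frontal-plane angle of the left->right tuber coxae line to the
            horizontal, positive right side down (axial rotation);
    pitch — sagittal-plane inclination of tuber sacrale -> inter-coxae
            midpoint, positive upward (flexion-extension);
    yaw   — dorsal-plane angle of the tuber coxae line, positive nose-left
            (lateral bending).

    Returns
    -------
    (roll, pitch, yaw) arrays in degrees.
    """
    ts = np.asarray(ts, float)
    d = np.asarray(rtc, float) - np.asarray(ltc, float)
    mid = (np.asarray(ltc, float) + np.asarray(rtc, float)) / 2.0

    dy = np.einsum("ij,ij->i", d, frame.yhat)
    dz = np.einsum("ij,ij->i", d, frame.zhat)
    dx = np.einsum("ij,ij->i", d, frame.xhat)
    if np.any(np.hypot(dy, dz) < 1e-9):
        raise DegenerateGeometryError("tuber coxae line degenerate in frontal plane")
    # left->right points along -yhat; measure from the rightward horizontal.
    roll = np.rad2deg(np.arctan2(-dz, -dy))
    yaw = np.rad2deg(np.arctan2(dx, -dy))

    v = mid - ts
    vx = np.einsum("ij,ij->i", v, frame.xhat)
    vz = np.einsum("ij,ij->i", v, frame.zhat)
    if np.any(np.hypot(vx, vz) < 1e-9):
        raise DegenerateGeometryError("pelvic pitch vector degenerate in sagittal plane")
    pitch = np.rad2deg(np.arctan2(vz, vx))
    return roll, pitch, yaw


# ---------------------------------------------------------------------------
# Back angles
# ---------------------------------------------------------------------------

#: Marker triples (cranial, apex, caudal) per back angle.  The whole-back
#: angle is the angle between the withers–T15 and T15–tuber sacrale
#: segments; segmental angles use the markers immediately cranial and
#: caudal to the one in question.
BACK_ANGLE_MARKERS: dict[str, tuple[str, str, str]] = {
    "whole_back": ("withers_mid", "T15", "tuber_sacrale"),
    "T12": ("withers_mid", "T12", "T15"),
    "T15": ("T12", "T15", "T18"),
    "T18": ("T15", "T18", "L3"),
    "L3": ("T18", "L3", "L5"),
    "L5": ("L3", "L5", "tuber_sacrale"),
    "ts": ("L5", "tuber_sacrale", "S5"),
}


def back_angle(
    cranial: np.ndarray,
    apex: np.ndarray,
    caudal: np.ndarray,
    frame: HorseFrame,
    plane: str,
) -> np.ndarray:
    """Signed deviation from collinearity of two projected spine segments.

    The cranial and caudal segments (cranial->apex, apex->caudal) are
    projected into the sagittal plane (flexion-extension) or the dorsal
    plane (lateral bending); 0 means a straight (collinear) spine.  Positive:
    apex below the chord (sagittal) or left of it (dorsal).  For an apex
    displaced perpendicular to the chord by ``h`` with half-chord ``c``, the
    angle is ``2*atan(h/c)``.  Invariant to global translation.
    """
    if plane not in ("sagittal", "dorsal"):
        raise ValueError("back angles live in the sagittal or dorsal plane")
    s1 = np.asarray(apex, float) - np.asarray(cranial, float)
    s2 = np.asarray(caudal, float) - np.asarray(apex, float)
    a1, b1 = _plane_coords(s1, frame, plane)
    a2, b2 = _plane_coords(s2, frame, plane)
    if np.any(np.hypot(a1, b1) < 1e-9) or np.any(np.hypot(a2, b2) < 1e-9):
        raise DegenerateGeometryError("zero-length projected spine segment")
    ang = _signed_angle(a1, b1, a2, b2)
    # With the cranial marker ahead in the direction of travel the segments
    # point along -xhat; in the (xhat, zhat) sagittal basis an apex below the
    # chord then comes out negative, so flip; the (xhat, yhat) dorsal basis
    # already gives positive for an apex to the left.
    return -ang if plane == "sagittal" else ang


# ---------------------------------------------------------------------------
# Body tracking, head swivel, speed
# ---------------------------------------------------------------------------


def body_tracking_angle(
    withers: np.ndarray,
    ts: np.ndarray,
    frame: HorseFrame,
) -> np.ndarray:
    """Dorsal-plane angle between the body axis and the direction of travel.

    The body axis runs from the pelvis (tuber sacrale) to the withers.
    Positive = forehand tracking to the right of travel (and hindquarters to
    the left).
    """
    d = np.asarray(withers, float) - np.asarray(ts, float)
    a, b = _plane_coords(d, frame, "dorsal")
    if np.any(np.hypot(a, b) < 1e-9):
        raise DegenerateGeometryError("degenerate body axis in dorsal plane")
    return np.rad2deg(np.arctan2(-b, a))


def head_swivel_angle(
    head: np.ndarray,
    withers: np.ndarray,
    ts: np.ndarray,
    frame: HorseFrame,
) -> np.ndarray:
    """Dorsal-plane angle between the cervical spine and the body axis.

    Neck = head -> withers... measured from withers; body = pelvis ->
    withers.  Positive = cervical bending to the right (proxy for cervical
    lateral bending).
    """
    neck = np.asarray(head, float) - np.asarray(withers, float)
    body = np.asarray(withers, float) - np.asarray(ts, float)
    bu, bw = _plane_coords(body, frame, "dorsal")
    nu, nw = _plane_coords(neck, frame, "dorsal")
    if np.any(np.hypot(bu, bw) < 1e-9) or np.any(np.hypot(nu, nw) < 1e-9):
        raise DegenerateGeometryError("degenerate neck or body axis")
    return -_signed_angle(bu, bw, nu, nw)


def speed_from_marker(
    ts_xy: np.ndarray,
    sampling_rate: float,
    window_s: float = 0.5,
) -> np.ndarray:
    """Speed (m/s) by smoothed differentiation of a horizontal track (mm)."""
    xy = np.asarray(ts_xy, dtype=float)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 frames for speed")
    vel = smoothed_derivative(xy, sampling_rate, window_s)
    return np.hypot(vel[:, 0], vel[:, 1]) / 1000.0


# ---------------------------------------------------------------------------
# Full parameter set
# ---------------------------------------------------------------------------

PARAMETER_UNITS: dict[str, str] = {
    "stride_duration": "sec",
    "stride_frequency": "Hz",
    "speed": "m/s",
    "head_rom": "mm",
    "withers_rom": "mm",
    "sacrum_rom": "mm",
    "pelvis_roll": "deg",
    "pelvis_pitch": "deg",
    "pelvis_yaw": "deg",
    "body_tracking": "deg",
    "head_swivel": "deg",
    "back_flex_ext": "deg",
    "back_lat_bend": "deg",
    "flex_ext_T12": "deg",
    "lat_bend_T12": "deg",
    "flex_ext_T15": "deg",
    "lat_bend_T15": "deg",
    "flex_ext_T18": "deg",
    "lat_bend_T18": "deg",
    "flex_ext_L3": "deg",
    "lat_bend_L3": "deg",
    "flex_ext_L5": "deg",
    "lat_bend_L5": "deg",
    "flex_ext_ts": "deg",
    "lat_bend_ts": "deg",
}

#: Parameters summarised as a per-stride signed mean rather than a ROM.
MEAN_PARAMETERS = ("body_tracking", "head_swivel", "speed")


def _marker_valid(series: MarkerFrameSeries, config: MarkerConfig,
                  roles: tuple[str, ...]) -> np.ndarray:
    valid = np.ones(series.n_frames, dtype=bool)
    for role in roles:
        valid &= ~series.gap_mask[config.label(role)]
    return valid


def _fill_gaps(pos: np.ndarray, gap: np.ndarray) -> np.ndarray:
    """Bridge gapped frames linearly so the IIR filter does not ring.

    This is a numerical aid only: gapped frames stay flagged invalid and the
    strides containing them are dropped downstream, never reported.
    """
    if not gap.any():
        return pos
    if gap.all():
        return np.zeros_like(pos)
    out = pos.copy()
    idx = np.arange(len(pos))
    for j in range(pos.shape[1]):
        out[gap, j] = np.interp(idx[gap], idx[~gap], pos[~gap, j])
    return out


def compute_angles(
    series: MarkerFrameSeries,
    config: MarkerConfig,
    frame: HorseFrame,
    cutoff_hz: float = 30.0,
    filter_order: int = 4,
) -> dict[str, AngleSeries]:
    """All per-frame kinematic series of the standard parameter set.

    Marker coordinates are low-pass filtered (gaps excluded from validity,
    not interpolated: filtered values on gapped stretches are unreliable and
    flagged invalid), then projected in the supplied horse frame — pass a
    lean-corrected frame to avoid projection errors on the circle.

    Returns a mapping parameter name -> :class:`AngleSeries`; the vertical
    displacement sources (head/withers/sacrum, mm) and speed (m/s) are
    included under the same container.
    """
    filt: dict[str, np.ndarray] = {}
    for role in config.roles:
        label = config.label(role)
        pos = _fill_gaps(series.positions[label], series.gap_mask[label])
        filt[role] = lowpass_filter(pos, cutoff_hz, series.sampling_rate,
                                    filter_order)

    def vld(*roles: str) -> np.ndarray:
        return _marker_valid(series, config, roles)

    out: dict[str, AngleSeries] = {}

    roll, pitch, yaw = pelvic_angles(
        filt["tuber_sacrale"], filt["tuber_coxae_left"],
        filt["tuber_coxae_right"], frame)
    pelvis_ok = vld("tuber_sacrale", "tuber_coxae_left", "tuber_coxae_right")
    out["pelvis_roll"] = AngleSeries("pelvis_roll", roll, pelvis_ok,
                                     sign_convention="positive right side down")
    out["pelvis_pitch"] = AngleSeries("pelvis_pitch", pitch, pelvis_ok,
                                      sign_convention="positive pointing up")
    out["pelvis_yaw"] = AngleSeries("pelvis_yaw", yaw, pelvis_ok,
                                    sign_convention="positive nose-left")

    name_map = {"whole_back": ("back_flex_ext", "back_lat_bend")}
    for key, (cr, ap, ca) in BACK_ANGLE_MARKERS.items():
        fe_name, lb_name = name_map.get(
            key, (f"flex_ext_{key}", f"lat_bend_{key}"))
        ok = vld(cr, ap, ca)
        fe = back_angle(filt[cr], filt[ap], filt[ca], frame, "sagittal")
        lb = back_angle(filt[cr], filt[ap], filt[ca], frame, "dorsal")
        out[fe_name] = AngleSeries(fe_name, fe, ok,
                                   sign_convention="positive apex below chord")
        out[lb_name] = AngleSeries(lb_name, lb, ok,
                                   sign_convention="positive apex left of chord")

    bt = body_tracking_angle(filt["withers_mid"], filt["tuber_sacrale"], frame)
    out["body_tracking"] = AngleSeries(
        "body_tracking", bt, vld("withers_mid", "tuber_sacrale"),
        sign_convention="positive forehand right of travel")
    hs = head_swivel_angle(filt["head_ref"], filt["withers_mid"],
                           filt["tuber_sacrale"], frame)
    out["head_swivel"] = AngleSeries(
        "head_swivel", hs, vld("head_ref", "withers_mid", "tuber_sacrale"),
        sign_convention="positive cervical bending right")

    for param, role in (("head_rom", "head_ref"), ("withers_rom", "withers_mid"),
                        ("sacrum_rom", "tuber_sacrale")):
        out[param] = AngleSeries(param, filt[role][:, 2], vld(role), units="mm")

    spd = speed_from_marker(filt["tuber_sacrale"][:, :2], series.sampling_rate)
    out["speed"] = AngleSeries("speed", spd, vld("tuber_sacrale"), units="m/s")
    return out
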