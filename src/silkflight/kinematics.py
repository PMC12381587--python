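"""Fourier representation of periodic wing/body kinematics and angle
extraction from 3-D landmark tracks.

Every periodic kinematic parameter (wing sweep phi, deviation theta,
feathering alpha, stroke-plane angle beta, body pitch chi, body velocity
components u and w) is represented as a truncated Fourier series

    y(t) = a0 + sum_{k=1..K} a_k cos(2 pi k f t) + b_k sin(2 pi k f t)

with K = 3 by default; third order consistently captures moth wingstroke
waveforms.  Angle waveforms carry degrees in all I/O; the aerodynamic core
converts to radians at evaluation time.

Angle extraction follows the tracked-marker geometry: body pitch from the
head/abdomen-tip axis, a per-wingstroke least-squares stroke plane fitted
to the wingtip path about the hinge, sweep/deviation as azimuth/elevation
of the hinge-to-tip vector in the stroke-plane frame, and feathering from
the wing plane spanned by hinge, wingtip and inner-angle markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FourierWaveform",
    "WingKinematics",
    "BodyKinematics",
    "LandmarkTrack",
    "fit_fourier",
    "fit_fourier_with_trend",
    "waveform_stats",
    "rescale_waveform",
    "phase_difference",
    "extract_kinematics",
    "segment_wingstrokes",
    "LANDMARK_NAMES",
]

LANDMARK_NAMES = (
    "head",
    "thorax_abdomen",
    "abdomen_tip",
    "hinge_L",
    "hinge_R",
    "wingtip_R",
    "inner_angle_R",
)

#: grid used for waveform statistics (mean, max-min amplitude)
STATS_GRID = 1024


@dataclass(frozen=True)
class FourierWaveform:
    """One periodic kinematic parameter: mean ``a0`` plus K harmonics at
    wingbeat frequency ``f`` (Hz).  Units are whatever the parameter
    carries (degrees for angles, m/s for velocities)."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    f: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.atleast_1d(np.asarray(self.a, float)))
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, float)))
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same length")

    # -- construction helpers ------------------------------------------------
    @classmethod
    def constant(cls, value: float, f: float, K: int = 3) -> "FourierWaveform":
        return cls(a0=float(value), a=np.zeros(K), b=np.zeros(K), f=f)

    @classmethod
    def cosine(cls, mean: float, half_amp: float, f: float, phase_deg: float = 0.0,
               K: int = 3) -> "FourierWaveform":
        """mean + half_amp * cos(2 pi f t - phase)."""
        a = np.zeros(K)
        b = np.zeros(K)
        ph = np.deg2rad(phase_deg)
        a[0] = half_amp * np.cos(ph)
        b[0] = half_amp * np.sin(ph)
        return cls(a0=float(mean), a=a, b=b, f=f)

    @property
    def K(self) -> int:
        return self.a.size

    @property
    def period(self) -> float:
        return 1.0 / self.f

    # -- evaluation ----------------------------------------------------------
    def __call__(self, t, deriv: int = 0):
        """Evaluate the series or its analytic 1st/2nd time derivative."""
        if deriv not in (0, 1, 2):
            raise ValueError("deriv must be 0, 1 or 2")
        t = np.asarray(t, float)
        k = np.arange(1, self.K + 1)
        w = 2.0 * np.pi * k * self.f  # (K,)
        arg = np.multiply.outer(t, w)  # (..., K)
        c, s = np.cos(arg), np.sin(arg)
        if deriv == 0:
            out = self.a0 + c @ self.a + s @ self.b
        elif deriv == 1:
            out = (-s * w) @ self.a + (c * w) @ self.b
        else:
            out = (-c * w**2) @ self.a + (-s * w**2) @ self.b
        return out if out.shape else float(out)

    def antiderivative(self, t):
        """Analytic time integral with value a0*t - sum(b_k/w_k) at t=0."""
        t = np.asarray(t, float)
        k = np.arange(1, self.K + 1)
        w = 2.0 * np.pi * k * self.f
        arg = np.multiply.outer(t, w)
        out = self.a0 * t + np.sin(arg) @ (self.a / w) - np.cos(arg) @ (self.b / w)
        return out if out.shape else float(out)

    # -- transforms ----------------------------------------------------------
    def with_frequency(self, f: float) -> "FourierWaveform":
        """Same shape on a rescaled time base (coefficients unchanged)."""
        return replace(self, f=float(f))

    def flattened(self) -> "FourierWaveform":
        """Constant waveform at the wingstroke mean (harmonics removed)."""
        return replace(self, a=np.zeros(self.K), b=np.zeros(self.K))

    def half_period_shifted(self) -> "FourierWaveform":
        """Time-shift by half a period: harmonic k gains a phase k*180 deg,
        i.e. odd-harmonic coefficients flip sign."""
        sgn = (-1.0) ** np.arange(1, self.K + 1)
        return replace(self, a=self.a * sgn, b=self.b * sgn)

    def fundamental_phase(self) -> float:
        """Phase lead delta (deg) of the fundamental written as
        A*cos(2 pi f t + delta)."""
        if self.K < 1 or (self.a[0] == 0.0 and self.b[0] == 0.0):
            raise ValueError("waveform has a zero fundamental harmonic")
        return float(np.rad2deg(np.arctan2(-self.b[0], self.a[0])))


@dataclass(frozen=True)
class WingKinematics:
    """Wing kinematic angles (deg) relative to the stroke plane, plus the
    stroke-plane angle beta and the constant stroke-plane roll betar."""

    phi: FourierWaveform
    theta: FourierWaveform
    alpha: FourierWaveform
    beta: FourierWaveform
    betar: float  # deg, constant over a wingstroke
    f: float

    def __post_init__(self) -> None:
        for wf in (self.phi, self.theta, self.alpha, self.beta):
            if not np.isclose(wf.f, self.f):
                raise ValueError("all wing waveforms must share the wingbeat frequency")


@dataclass(frozen=True)
class BodyKinematics:
    """Body pitch chi (deg) and global-frame COM velocities u (fore-aft)
    and w (vertical), m/s.  Lateral velocity is identically zero in steady
    symmetric forward flight."""

    chi: FourierWaveform
    u: FourierWaveform
    w: FourierWaveform
    v_lat: float = 0.0

    @property
    def f(self) -> float:
        return self.chi.f


@dataclass
class LandmarkTrack:
    """3-D positions (m) of the seven tracked body/wing points per frame."""

    points: dict  # name -> (n_frames, 3) array
    frame_rate: float

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"landmark track missing points: {missing}")
        n = {self.points[k].shape[0] for k in LANDMARK_NAMES}
        if len(n) != 1:
            raise ValueError("all landmark series must have the same length")
        for k in LANDMARK_NAMES:
            if not np.all(np.isfinite(self.points[k])):
                raise ValueError(f"non-finite coordinates in landmark '{k}'")

    @property
    def n_frames(self) -> int:
        return self.points["head"].shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def to_csv(self, path) -> None:
        rows = []
        for name in LANDMARK_NAMES:
            p = self.points[name]
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(p.shape[0]),
                        "point_name": name,
                        "x_m": p[:, 0],
                        "y_m": p[:, 1],
                        "z_m": p[:, 2],
                    }
                )
            )
        pd.concat(rows).sort_values(["frame", "point_name"]).to_csv(path, index=False)
        Path(path).with_suffix(".json").write_text(
            json.dumps({"frame_rate_hz": self.frame_rate})
        )

    @classmethod
    def from_csv(cls, path, frame_rate: float | None = None) -> "LandmarkTrack":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"landmark file not found: {path}")
        df = pd.read_csv(path)
        for col in ("frame", "point_name", "x_m", "y_m", "z_m"):
            if col not in df.columns:
                raise ValueError(f"landmark CSV {path} missing column '{col}'")
        if frame_rate is None:
            sidecar = path.with_suffix(".json")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"frame_rate not given and sidecar not found: {sidecar}"
                )
            frame_rate = float(json.loads(sidecar.read_text())["frame_rate_hz"])
        points = {}
        for name, g in df.groupby("point_name"):
            g = g.sort_values("frame")
            points[name] = g[["x_m", "y_m", "z_m"]].to_numpy()
        return cls(points=points, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# Fitting and waveform manipulation


def fit_fourier(t, y, f: float, K: int = 3) -> FourierWaveform:
    """Least-squares fit of an order-K Fourier series at known frequency f.

    Requires at least 2K+1 samples; solved via the linear design matrix
    [1, cos(k w t), sin(k w t)].
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 2 * K + 1:
        raise ValueError(f"need at least {2 * K + 1} samples for an order-{K} fit")
    k = np.arange(1, K + 1)
    arg = np.multiply.outer(t, 2.0 * np.pi * k * f)
    A = np.hstack([np.ones((t.size, 1)), np.cos(arg), np.sin(arg)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return FourierWaveform(a0=coef[0], a=coef[1 : K + 1], b=coef[K + 1 :], f=f)


def fit_fourier_with_trend(t, y, f: float, K: int = 3):
    """Fit ``c0 + c1*t + Fourier(K)``; returns (slope c1, FourierWaveform).

    Used for COM positions, whose mean velocity appears as a linear drift
    on top of the periodic bobbing; the velocity is then the analytic
    derivative ``c1 + series'(t)``.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 2 * K + 2:
        raise ValueError(f"need at least {2 * K + 2} samples")
    k = np.arange(1, K + 1)
    arg = np.multiply.outer(t, 2.0 * np.pi * k * f)
    A = np.hstack([np.ones((t.size, 1)), t[:, None], np.cos(arg), np.sin(arg)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[1])
    wf = FourierWaveform(a0=coef[0], a=coef[2 : K + 2], b=coef[K + 2 :], f=f)
    return slope, wf


def waveform_stats(wf: FourierWaveform, n_grid: int = STATS_GRID):
    """(mean, amplitude) over one period on a uniform grid.

    The mean is the grid average (equal to ``a0`` for any grid finer than
    the harmonic content); the amplitude is max - min of the waveform,
    the convention used for the trim-search parameters.
    """
    if n_grid < 256:
        raise ValueError("n_grid must be >= 256")
    t = np.arange(n_grid) / (n_grid * wf.f)
    y = wf(t)
    return float(np.mean(y)), float(np.max(y) - np.min(y))


def rescale_waveform(
    wf: FourierWaveform, new_mean: float, new_amplitude: float
) -> FourierWaveform:
    """Shift/scale a waveform to a target mean and max-min amplitude,
    preserving its shape (harmonic ratios and phases)."""
    _, amp = waveform_stats(wf)
    if new_amplitude == 0.0:
        return FourierWaveform.constant(new_mean, wf.f, wf.K)
    if amp == 0.0:
        raise ValueError("cannot rescale a constant waveform to nonzero amplitude")
    s = new_amplitude / amp
    return FourierWaveform(a0=float(new_mean), a=wf.a * s, b=wf.b * s, f=wf.f)


def phase_difference(wf_a: FourierWaveform, wf_b: FourierWaveform) -> float:
    """Fundamental-harmonic phase difference (deg, in [0, 360)).

    Each waveform's fundamental is written ``A cos(2 pi f t + delta)``;
    the result is ``(delta_a - delta_b) mod 360``, i.e. how far waveform
    a leads waveform b.  Invariant to amplitude rescaling of either input.
    """
    d = wf_a.fundamental_phase() - wf_b.fundamental_phase()
    return float(np.mod(d, 360.0))


# ---------------------------------------------------------------------------
# Angle extraction from landmark tracks


def _plane_normal(p: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through points p (n,3),
    free offset, via PCA (smallest principal direction)."""
    q = p - p.mean(axis=0)
    # smallest right singular vector
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    n = vt[-1]
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) wingtip path: no stroke plane")
    return n


def _stroke_plane_angles(normal: np.ndarray) -> tuple[float, float]:
    """(beta, betar) in radians from a stroke-plane unit normal.

    The stroke-plane frame is the global frame pitched by beta about the
    y-axis (normal tilting toward +x, forward) then rolled by betar about
    its x-axis, so the normal in global coordinates is
    (sin(beta) cos(betar), -sin(betar), cos(beta) cos(betar)).
    """
    n = np.asarray(normal, float)
    if n[2] < 0:
        n = -n
    betar = float(np.arcsin(np.clip(-n[1], -1.0, 1.0)))
    beta = float(np.arctan2(n[0], n[2]))
    return beta, betar


def _stroke_frame(beta: float, betar: float) -> np.ndarray:
    """Rotation matrix whose columns are the stroke-plane axes in global
    coordinates (angles in radians)."""
    cb, sb = np.cos(beta), np.sin(beta)
    cr, sr = np.cos(betar), np.sin(betar)
    Ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, cr, -sr], [0.0, sr, cr]])
    return Ry @ Rx


def _provisional_sweep(track: LandmarkTrack) -> np.ndarray:
    """Unwrapped sweep angle (rad) of the wingtip about the hinge in a
    stroke plane fitted to the whole track."""
    p = track.points["wingtip_R"] - track.points["hinge_R"]
    normal = _plane_normal(p)
    beta, betar = _stroke_plane_angles(normal)
    Rgs = _stroke_frame(beta, betar)
    ps = p @ Rgs  # rows: tip vector in stroke frame
    return np.unwrap(np.arctan2(-ps[:, 0], ps[:, 1]))


def _refine_frequency(t: np.ndarray, phi: np.ndarray, f0: float, K: int = 3) -> float:
    """Refine a wingbeat-frequency estimate by minimizing the Fourier-fit
    residual of the high-amplitude sweep series over f."""
    from scipy.optimize import minimize_scalar

    def ssr(f):
        wf = fit_fourier(t, phi, f=f, K=K)
        r = phi - wf(t)
        return float(r @ r)

    res = minimize_scalar(
        ssr, bounds=(0.9 * f0, 1.1 * f0), method="bounded",
        options={"xatol": 1e-12 * f0},
    )
    return float(res.x)


def segment_wingstrokes(track: LandmarkTrack) -> tuple[np.ndarray, float]:
    """Locate wingstroke boundaries at dorsal stroke reversals.

    A provisional stroke plane is fitted to the whole wingtip path; the
    provisional sweep angle's maxima (dorsal reversals) define stroke
    boundaries.  The wingbeat frequency from the mean peak spacing is
    refined against the sweep series' Fourier-fit residual.  Returns
    (peak frame indices, wingbeat frequency Hz).
    """
    phi = _provisional_sweep(track)
    # dorsal reversal = sweep maximum; enforce a minimum spacing of a
    # quarter of the dominant cycle estimated from zero crossings
    approx = max(4, int(0.25 * track.n_frames / max(1, _count_cycles(phi))))
    peaks, _ = find_peaks(phi, distance=approx, prominence=0.3 * np.ptp(phi))
    if peaks.size < 2:
        raise ValueError("could not identify at least one full wingstroke")
    f0 = track.frame_rate / float(np.mean(np.diff(peaks)))
    f = _refine_frequency(track.times, phi, f0)
    return peaks, f


def _count_cycles(x: np.ndarray) -> int:
    xc = x - np.mean(x)
    crossings = np.sum(np.abs(np.diff(np.signbit(xc))))
    return max(1, int(crossings // 2))


def extract_kinematics(
    track: LandmarkTrack,
    com_point: str = "thorax_abdomen",
    K: int = 3,
    inner_angle_trailing: bool = True,
) -> pd.DataFrame:
    """Extract body/wing kinematic time series from a landmark track.

    Returns a DataFrame with columns ``t_s, stroke, chi_deg, beta_deg,
    betar_deg, phi_deg, theta_deg, alpha_deg, u_ms, w_ms`` covering the
    complete wingstrokes found in the track.  The stroke plane (hence
    beta, betar) is fitted per wingstroke; chi comes from the
    head/abdomen-tip axis; u and w from the analytic derivative of a
    linear-plus-Fourier fit to the COM-proxy trajectory.

    ``inner_angle_trailing`` states the convention that the inner-angle
    marker lies on the trailing side of the wing-pitching axis, which
    fixes the sign of the feathering angle.
    """
    t_all = track.times
    peaks, f = segment_wingstrokes(track)

    # body pitch from the head -> abdomen-tip axis, elevation above horizontal
    axis = track.points["head"] - track.points["abdomen_tip"]
    chi = np.rad2deg(
        np.arctan2(axis[:, 2], np.hypot(axis[:, 0], axis[:, 1]))
    )

    # COM-proxy velocities from linear + Fourier position fits
    com = track.points[com_point]
    su, wf_x = fit_fourier_with_trend(t_all, com[:, 0], f, K)
    sw, wf_z = fit_fourier_with_trend(t_all, com[:, 2], f, K)
    u = su + wf_x(t_all, deriv=1)
    w = sw + wf_z(t_all, deriv=1)

    p = track.points["wingtip_R"] - track.points["hinge_R"]
    q = track.points["inner_angle_R"] - track.points["hinge_R"]

    frames = []
    for k0, k1 in zip(peaks[:-1], peaks[1:]):
        sl = slice(k0, k1 + 1)
        normal = _plane_normal(p[sl])
        beta, betar = _stroke_plane_angles(normal)
        Rgs = _stroke_frame(beta, betar)
        ps = p[sl] @ Rgs
        qs = q[sl] @ Rgs
        r = np.linalg.norm(ps, axis=1)
        phi = np.arctan2(-ps[:, 0], ps[:, 1])
        theta = np.arcsin(np.clip(ps[:, 2] / r, -1.0, 1.0))
        # undo sweep and deviation on the inner-angle vector, leaving the
        # pure feathering rotation about the spanwise axis
        cph, sph = np.cos(phi), np.sin(phi)
        cth, sth = np.cos(theta), np.sin(theta)
        qx = cph * qs[:, 0] + sph * qs[:, 1]
        qy = -sph * qs[:, 0] + cph * qs[:, 1]
        qz = qs[:, 2]
        q2x = qx
        q2z = -sth * qy + cth * qz
        if inner_angle_trailing:
            alpha = np.arctan2(-q2z, -q2x)
        else:
            alpha = np.arctan2(q2z, q2x)
        frames.append(
            pd.DataFrame(
                {
                    "t_s": t_all[sl],
                    "stroke": np.full(k1 - k0 + 1, len(frames)),
                    "chi_deg": chi[sl],
                    "beta_deg": np.rad2deg(beta),
                    "betar_deg": np.rad2deg(betar),
                    "phi_deg": np.rad2deg(phi),
                    "theta_deg": np.rad2deg(theta),
                    "alpha_deg": np.rad2deg(alpha),
                    "u_ms": u[sl],
                    "w_ms": w[sl],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["wingbeat_frequency_hz"] = f
    return out
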