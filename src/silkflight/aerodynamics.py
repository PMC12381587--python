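"""Quasi-steady blade-element aerodynamics of a flapping moth wing.

The wing is a rigid flat plate discretized into spanwise strips.  At each
instant the force on a strip of width ``dr`` and chord ``c`` is the sum of

* translational lift   |dF_L| = 1/2 rho CL v^2 c dr, perpendicular to the
  relative airflow, in the plane of the airflow and the wing normal, on
  the suction side;
* translational drag   |dF_D| = 1/2 rho CD v^2 c dr, along the relative
  airflow;
* rotational force     dF_rot = rho CR v c^2 alphah_dot dr, along the wing
  normal (Kramer effect from wing pitching in the global frame);
* added-mass force     dF_adm = -1/4 pi rho [(phi_dd sin(alpha)
  + phi_d alphah_dot cos(alpha)) r c^2 + 1/4 alphah_dd c^3] dr along the
  wing normal (reaction opposing the normal acceleration of the entrained
  air).

Here ``v`` is the relative airflow speed at the strip's pitching-axis
point measured in the global frame (zero ambient wind by default), CL and
CD are empirical polynomials in the angle of attack measured on
dynamically scaled hawkmoth wings, CR = pi (0.75 - e/c) with the
pitching axis at chord fraction e/c, and alphah = alpha - beta is the wing
inclination to the absolute horizontal (its rate is the wing-pitching
angular velocity in the global frame).

Frames: global (x forward, z up), body (pitched chi about y, nose-up
positive), stroke plane (inclined beta to the horizontal about the
y-axis, rolled betar about its x-axis, mirrored for the left side,
anchored at the hinge), and wing (sweep phi about the stroke-plane
normal, deviation theta, feathering alpha about the spanwise axis).
Sign conventions: at beta = 90 deg the stroke plane is vertical with its
normal along +x; positive sweep carries the wingtip toward the dorsal
(up-backward) side, so the dorsal stroke reversal is the sweep maximum
and the downstroke (phi decreasing) travels down-forward; positive
feathering tilts the leading edge up relative to the stroke plane, with
the wing inclination to the horizontal alphah = alpha - beta.  All
rotation derivatives are analytic — no finite differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .kinematics import BodyKinematics, FourierWaveform, WingKinematics
from .morphology import MorphoScalars, WingMorphology, derive_scalars

__all__ = [
    "MothConfiguration",
    "StripState",
    "ForceDecomposition",
    "WingstrokeResult",
    "frame_chain",
    "strip_state",
    "lift_drag_coeffs",
    "rotational_coeff",
    "strip_forces",
    "total_aero",
    "inertial_force",
    "aero_power",
    "simulate_wingstroke",
]

RHO_AIR = 1.225  # kg/m^3
GRAVITY = 9.81  # m/s^2

# empirical translational coefficient polynomials (hawkmoth flat-plate data)
_CL_1, _CL_2 = 1.552, 1.725
_CD_1, _CD_2 = 0.0596, 3.598


@dataclass
class MothConfiguration:
    """Everything needed to simulate one moth's wingstroke."""

    morph: WingMorphology
    wing_kin: WingKinematics
    body_kin: BodyKinematics
    mt: float  # total mass, kg
    kL: float = 1.0
    kD: float = 1.0
    rho: float = RHO_AIR
    g: float = GRAVITY
    ambient_wind: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scalars: Optional[MorphoScalars] = None

    def __post_init__(self) -> None:
        if self.kL <= 0 or self.kD <= 0:
            raise ValueError("kL and kD must be positive")
        if self.rho <= 0 or self.g <= 0:
            raise ValueError("rho and g must be positive")
        self.ambient_wind = np.asarray(self.ambient_wind, float)
        if self.scalars is None:
            self.scalars = derive_scalars(self.morph, self.mt)

    @property
    def f(self) -> float:
        return self.wing_kin.f

    @property
    def weight(self) -> float:
        return self.mt * self.g

    def replace(self, **kw) -> "MothConfiguration":
        cfg = replace(self, **kw)
        if "morph" in kw or "mt" in kw:
            cfg.scalars = derive_scalars(cfg.morph, cfg.mt)
        return cfg


@dataclass
class StripState:
    """Instantaneous kinematic state of one wing strip."""

    position: np.ndarray  # m, global, relative to the COM
    velocity: np.ndarray  # m/s, global
    chord_dir: np.ndarray  # unit, trailing -> leading edge
    normal: np.ndarray  # unit wing normal
    airflow: np.ndarray  # unit relative-airflow direction (zero if v == 0)
    speed: float  # m/s
    alpha_v_deg: float  # angle of attack, [0, 180]
    alpha_h_deg: float  # wing inclination to horizontal
    flow_defined: bool = True


@dataclass
class ForceDecomposition:
    """Force components on a strip (N), with the frame they are expressed in."""

    F_L: np.ndarray
    F_D: np.ndarray
    F_rot: np.ndarray
    F_adm: np.ndarray
    frame: str = "global"

    @property
    def total(self) -> np.ndarray:
        return self.F_L + self.F_D + self.F_rot + self.F_adm


# ---------------------------------------------------------------------------
# Elementary rotation series with analytic first/second time derivatives

def _trig(wf: FourierWaveform, t: np.ndarray, degrees: bool = True):
    """(angle, rate, accel) in radians from a waveform, vectorized over t."""
    k = np.pi / 180.0 if degrees else 1.0
    return wf(t) * k, wf(t, 1) * k, wf(t, 2) * k


def _rot_series(kind: str, psi, dpsi=None, ddpsi=None):
    """Stacked rotation matrices R(t) (T,3,3) and their time derivatives.

    kind: 'y-' = Rot_y(-psi), 'y+' = Rot_y(psi), 'x+' = Rot_x(psi),
    'z+' = Rot_z(psi).  If dpsi is None the angle is constant and the
    derivative matrices are zero.
    """
    psi = np.atleast_1d(np.asarray(psi, float))
    T = psi.size
    c, s = np.cos(psi), np.sin(psi)
    if dpsi is None:
        cd = sd = cdd = sdd = np.zeros(T)
    else:
        dpsi = np.broadcast_to(np.asarray(dpsi, float), psi.shape)
        ddpsi = np.broadcast_to(np.asarray(ddpsi, float), psi.shape)
        cd, sd = -s * dpsi, c * dpsi
        cdd = -c * dpsi**2 - s * ddpsi
        sdd = -s * dpsi**2 + c * ddpsi

    def fill(cc, ss, const):
        R = np.zeros((T, 3, 3))
        if kind == "y-":
            R[:, 0, 0] = cc; R[:, 0, 2] = -ss
            R[:, 1, 1] = const
            R[:, 2, 0] = ss; R[:, 2, 2] = cc
        elif kind == "y+":
            R[:, 0, 0] = cc; R[:, 0, 2] = ss
            R[:, 1, 1] = const
            R[:, 2, 0] = -ss; R[:, 2, 2] = cc
        elif kind == "x+":
            R[:, 0, 0] = const
            R[:, 1, 1] = cc; R[:, 1, 2] = -ss
            R[:, 2, 1] = ss; R[:, 2, 2] = cc
        elif kind == "z+":
            R[:, 0, 0] = cc; R[:, 0, 1] = -ss
            R[:, 1, 0] = ss; R[:, 1, 1] = cc
            R[:, 2, 2] = const
        else:  # pragma: no cover
            raise ValueError(kind)
        return R

    return fill(c, s, 1.0), fill(cd, sd, 0.0), fill(cdd, sdd, 0.0)


# y-mirror conjugation mask: flips matrix elements coupling y to x/z
_MIRROR_MASK = np.array(
    [[1.0, -1.0, 1.0], [-1.0, 1.0, -1.0], [1.0, -1.0, 1.0]]
)
_MIRROR = np.diag([1.0, -1.0, 1.0])


def _chain(config: MothConfiguration, t: np.ndarray):
    """Evaluate the full kinematic chain on a time grid.

    Returns a dict of stacked arrays: rotation triples for the
    global->stroke ('A'), stroke->wing ('B'), global->wing ('W') and
    global->body ('C') transforms for the right wing (left-wing versions
    follow by mirror conjugation), plus the angle/rate/accel series.
    """
    t = np.atleast_1d(np.asarray(t, float))
    wk, bk = config.wing_kin, config.body_kin
    beta, dbeta, ddbeta = _trig(wk.beta, t)
    phi, dphi, ddphi = _trig(wk.phi, t)
    theta, dtheta, ddtheta = _trig(wk.theta, t)
    alpha, dalpha, ddalpha = _trig(wk.alpha, t)
    chi, dchi, ddchi = _trig(bk.chi, t)
    betar = np.deg2rad(wk.betar)

    P, Pd, Pdd = _rot_series("y+", beta, dbeta, ddbeta)
    Xr, _, _ = _rot_series("x+", np.full_like(beta, betar))
    A, Ad, Add = P @ Xr, Pd @ Xr, Pdd @ Xr

    Z, Zd, Zdd = _rot_series("z+", phi, dphi, ddphi)
    X, Xd, Xdd = _rot_series("x+", theta, dtheta, ddtheta)
    Y, Yd, Ydd = _rot_series("y-", alpha, dalpha, ddalpha)
    B = Z @ X @ Y
    Bd = Zd @ X @ Y + Z @ Xd @ Y + Z @ X @ Yd
    Bdd = (
        Zdd @ X @ Y + Z @ Xdd @ Y + Z @ X @ Ydd
        + 2.0 * (Zd @ Xd @ Y + Zd @ X @ Yd + Z @ Xd @ Yd)
    )

    W = A @ B
    Wd = Ad @ B + A @ Bd
    Wdd = Add @ B + 2.0 * Ad @ Bd + A @ Bdd

    C, Cd, Cdd = _rot_series("y-", chi, dchi, ddchi)

    u, du = bk.u(t), bk.u(t, 1)
    w, dw = bk.w(t), bk.w(t, 1)
    Tn = t.size
    v_com = np.zeros((Tn, 3))
    v_com[:, 0], v_com[:, 2] = u, w
    a_com = np.zeros((Tn, 3))
    a_com[:, 0], a_com[:, 2] = du, dw

    return {
        "t": t,
        "A": (A, Ad, Add),
        "B": (B, Bd, Bdd),
        "W": (W, Wd, Wdd),
        "C": (C, Cd, Cdd),
        "angles": {
            "beta": (beta, dbeta, ddbeta),
            "phi": (phi, dphi, ddphi),
            "theta": (theta, dtheta, ddtheta),
            "alpha": (alpha, dalpha, ddalpha),
            "chi": (chi, dchi, ddchi),
        },
        "alpha_h": (alpha - beta, dalpha - dbeta, ddalpha - ddbeta),
        "v_com": v_com,
        "a_com": a_com,
    }


def _side_frames(ch: dict, side: str):
    """(W, Wd, Wdd, C-triple, span sign) for one side; the left wing is
    the y-mirror conjugate of the right-wing chain."""
    W, Wd, Wdd = ch["W"]
    if side == "right":
        return W, Wd, Wdd, 1.0
    if side == "left":
        m = _MIRROR_MASK
        return W * m, Wd * m, Wdd * m, -1.0
    raise ValueError("side must be 'left' or 'right'")


def frame_chain(
    wing_kin: WingKinematics,
    body_kin: BodyKinematics,
    t,
    side: str = "right",
    morph: Optional[WingMorphology] = None,
):
    """Transforms of the kinematic chain at time(s) t for one wing.

    Returns a dict with stacked (T,3,3) rotations whose columns are the
    frame axes in global coordinates: ``R_gs`` (stroke plane), ``R_gw``
    (wing), ``R_gb`` (body), their time derivatives ``*_dot``, and the
    wing angular velocity ``omega`` (rad/s, global) recovered from
    ``Rdot R^T``.
    """
    cfg = MothConfiguration(
        morph=morph
        if morph is not None
        else WingMorphology(
            R=1.0, strip_centres=np.array([0.5]), dr=1.0,
            chord=np.array([0.0]), pitch_axis_frac=np.array([0.25]),
        ),
        wing_kin=wing_kin,
        body_kin=body_kin,
        mt=1.0,
    )
    ch = _chain(cfg, t)
    W, Wd, Wdd, _ = _side_frames(ch, side)
    A, Ad, _ = ch["A"]
    if side == "left":
        A, Ad = A * _MIRROR_MASK, Ad * _MIRROR_MASK
    C, Cd, _ = ch["C"]
    skew = Wd @ np.swapaxes(W, 1, 2)
    omega = np.stack(
        [skew[:, 2, 1], skew[:, 0, 2], skew[:, 1, 0]], axis=-1
    )
    return {
        "R_gs": A, "R_gs_dot": Ad,
        "R_gw": W, "R_gw_dot": Wd, "R_gw_ddot": Wdd,
        "R_gb": C, "R_gb_dot": Cd,
        "omega": omega,
    }


# ---------------------------------------------------------------------------
# Coefficients

def lift_drag_coeffs(alpha_v_deg, kL: float = 1.0, kD: float = 1.0):
    """Empirical flat-plate lift/drag coefficients vs angle of attack.

    CL = kL (1.552 sin a cos a + 1.725 sin^2 a cos a)
    CD = kD (0.0596 sin a cos a + 3.598 sin^3 a)
    """
    a = np.deg2rad(np.asarray(alpha_v_deg, float))
    s, c = np.sin(a), np.cos(a)
    CL = kL * (_CL_1 * s * c + _CL_2 * s * s * c)
    CD = kD * (_CD_1 * s * c + _CD_2 * s**3)
    return CL, CD


def rotational_coeff(pitch_axis_frac):
    """Theoretical rotational coefficient CR = pi (0.75 - e/c)."""
    e = np.asarray(pitch_axis_frac, float)
    if np.any((e < 0) | (e > 1)):
        raise ValueError("pitch_axis_frac must lie in [0, 1]")
    out = np.pi * (0.75 - e)
    return float(out) if out.shape == () else out


# ---------------------------------------------------------------------------
# Core vectorized wing computation

def _wing_arrays(config: MothConfiguration, ch: dict, side: str, morph: WingMorphology):
    """All per-strip kinematic and force arrays for one wing.

    Shapes: time T x strips N.  Returns a dict of arrays (vectors have a
    trailing axis of 3, global frame).
    """
    W, Wd, Wdd, s_sign = _side_frames(ch, side)
    C, Cd, Cdd = ch["C"]
    r = morph.strip_centres  # (N,)
    c = morph.chord
    dr = morph.dr
    N = r.size

    h = morph.hinge_offset * np.array([1.0, s_sign, 1.0])
    hinge_pos = C @ h  # (T,3), relative to COM
    hinge_vel = ch["v_com"] + Cd @ h
    hinge_acc = ch["a_com"] + Cdd @ h

    span = W[:, :, 1]  # (T,3) wing-frame y axis in global
    span_d = Wd[:, :, 1]
    span_dd = Wdd[:, :, 1]
    rr = (s_sign * r)[None, :, None]  # (1,N,1)

    pos = hinge_pos[:, None, :] + span[:, None, :] * rr  # (T,N,3)
    vel = hinge_vel[:, None, :] + span_d[:, None, :] * rr
    acc = hinge_acc[:, None, :] + span_dd[:, None, :] * rr

    bhat = W[:, :, 0]  # chord direction, trailing -> leading (T,3)
    nhat = W[:, :, 2]  # wing normal

    v_air = config.ambient_wind[None, None, :] - vel  # (T,N,3)
    speed = np.linalg.norm(v_air, axis=-1)  # (T,N)
    ok = speed > 1e-12
    vhat = np.where(ok[..., None], v_air / np.where(ok, speed, 1.0)[..., None], 0.0)

    dot_bv = np.einsum("tc,tnc->tn", bhat, vhat)
    alpha_v = np.arccos(np.clip(-dot_bv, -1.0, 1.0))  # rad, [0, pi]

    sa, ca = np.sin(alpha_v), np.cos(alpha_v)
    CL = config.kL * (_CL_1 * sa * ca + _CL_2 * sa * sa * ca)
    CD = config.kD * (_CD_1 * sa * ca + _CD_2 * sa**3)

    q = 0.5 * config.rho * speed**2 * c[None, :] * dr  # (T,N)
    F_D = (q * CD)[..., None] * vhat

    dot_nv = np.einsum("tc,tnc->tn", nhat, vhat)
    n_perp = nhat[:, None, :] - dot_nv[..., None] * vhat
    npn = np.linalg.norm(n_perp, axis=-1)
    okl = ok & (npn > 1e-9)
    lhat = np.where(
        okl[..., None],
        np.sign(dot_nv)[..., None] * n_perp / np.where(okl, npn, 1.0)[..., None],
        0.0,
    )
    F_L = (q * CL)[..., None] * lhat

    ah, dah, ddah = ch["alpha_h"]
    CR = rotational_coeff(morph.pitch_axis_frac)  # (N,)
    rot_mag = config.rho * CR[None, :] * speed * c[None, :] ** 2 * dah[:, None] * dr
    F_rot = rot_mag[..., None] * nhat[:, None, :]

    alpha = ch["angles"]["alpha"][0]
    phi_d, phi_dd = ch["angles"]["phi"][1], ch["angles"]["phi"][2]
    brace = (phi_dd * np.sin(alpha) + phi_d * dah * np.cos(alpha))[:, None] * (
        r[None, :] * c[None, :] ** 2
    ) + 0.25 * ddah[:, None] * c[None, :] ** 3
    adm_mag = -0.25 * np.pi * config.rho * brace * dr
    F_adm = adm_mag[..., None] * nhat[:, None, :]

    return {
        "pos": pos, "vel": vel, "acc": acc,
        "v_air": v_air, "speed": speed, "vhat": vhat,
        "bhat": bhat, "nhat": nhat,
        "alpha_v": alpha_v, "CL": CL, "CD": CD,
        "F_L": F_L, "F_D": F_D, "F_rot": F_rot, "F_adm": F_adm,
        "alpha_h": ah,
    }


# ---------------------------------------------------------------------------
# Public per-instant operations (wrappers over the vectorized core)

def strip_state(config: MothConfiguration, t: float, strip: int, side: str = "right") -> StripState:
    """Kinematic state of strip ``strip`` at time ``t``."""
    morph = config.morph
    if not 0 <= strip < morph.n_strips:
        raise IndexError("strip index out of range")
    ch = _chain(config, np.array([t]))
    wa = _wing_arrays(config, ch, side, morph)
    i = strip
    speed = float(wa["speed"][0, i])
    return StripState(
        position=wa["pos"][0, i],
        velocity=wa["vel"][0, i],
        chord_dir=wa["bhat"][0],
        normal=wa["nhat"][0],
        airflow=wa["vhat"][0, i],
        speed=speed,
        alpha_v_deg=float(np.rad2deg(wa["alpha_v"][0, i])),
        alpha_h_deg=float(np.rad2deg(wa["alpha_h"][0])),
        flow_defined=speed > 1e-12,
    )


def strip_forces(config: MothConfiguration, t: float, strip: int, side: str = "right") -> ForceDecomposition:
    """Force decomposition on one strip at time ``t`` (global frame)."""
    morph = config.morph
    if not 0 <= strip < morph.n_strips:
        raise IndexError("strip index out of range")
    ch = _chain(config, np.array([t]))
    wa = _wing_arrays(config, ch, side, morph)
    i = strip
    return ForceDecomposition(
        F_L=wa["F_L"][0, i], F_D=wa["F_D"][0, i],
        F_rot=wa["F_rot"][0, i], F_adm=wa["F_adm"][0, i],
        frame="global",
    )


def total_aero(config: MothConfiguration, t):
    """Total aerodynamic force and moment (about the COM), both wings,
    global frame.  Vectorized over t; scalar t gives (3,) vectors."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    ch = _chain(config, t_arr)
    F = np.zeros((t_arr.size, 3))
    M = np.zeros((t_arr.size, 3))
    for side in ("right", "left"):
        wa = _wing_arrays(config, ch, side, config.morph)
        Fw = wa["F_L"] + wa["F_D"] + wa["F_rot"] + wa["F_adm"]
        F += Fw.sum(axis=1)
        M += np.cross(wa["pos"], Fw).sum(axis=1)
    if np.isscalar(t) or np.asarray(t).shape == ():
        return F[0], M[0]
    return F, M


def inertial_force(config: MothConfiguration, t):
    """Reaction force on the body from wing-strip accelerations,
    dF = -(mw/S) c dr a_strip summed over strips and wings (global)."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    ch = _chain(config, t_arr)
    m_strip = config.morph.strip_mass  # (N,)
    F = np.zeros((t_arr.size, 3))
    for side in ("right", "left"):
        wa = _wing_arrays(config, ch, side, config.morph)
        F += -(m_strip[None, :, None] * wa["acc"]).sum(axis=1)
    if np.isscalar(t) or np.asarray(t).shape == ():
        return F[0]
    return F


def aero_power(config: MothConfiguration, t):
    """Aerodynamic power P = sum (dF_D + dF_rot + dF_adm) . v over strips
    and wings (W).  Lift is excluded: it is perpendicular to the airflow."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    ch = _chain(config, t_arr)
    P = np.zeros(t_arr.size)
    for side in ("right", "left"):
        wa = _wing_arrays(config, ch, side, config.morph)
        Fp = wa["F_D"] + wa["F_rot"] + wa["F_adm"]
        P += np.einsum("tnc,tnc->t", Fp, wa["v_air"])
    if np.isscalar(t) or np.asarray(t).shape == ():
        return float(P[0])
    return P


# ---------------------------------------------------------------------------
# Wingstroke simulation

@dataclass
class WingstrokeResult:
    """Time-resolved forces, moment, power and wingstroke averages.

    All force series are global-frame (N), summed over strips and both
    wings; the moment is about the COM (N m); power in W.  ``traces``
    holds strip-level diagnostics of the right wing: plain strip-averaged
    angle of attack and airflow speed, the (strip-independent) wing
    inclination, and area-weighted CL/CD means used for the lift-to-drag
    ratio.
    """

    times: np.ndarray
    F_total: np.ndarray
    F_lift: np.ndarray
    F_drag: np.ndarray
    F_rot: np.ndarray
    F_adm: np.ndarray
    M_total: np.ndarray
    F_inertial: np.ndarray
    P_aer: np.ndarray
    P_drag: np.ndarray
    P_rot: np.ndarray
    P_adm: np.ndarray
    P_lift_residual: np.ndarray  # numerically ~0: lift . airflow
    traces: pd.DataFrame
    config: "MothConfiguration"

    # -- averages ------------------------------------------------------------
    @property
    def F_mean(self) -> np.ndarray:
        return self.F_total.mean(axis=0)

    @property
    def Fx_mean(self) -> float:
        return float(self.F_mean[0])

    @property
    def Fz_mean(self) -> float:
        return float(self.F_mean[2])

    @property
    def My_mean(self) -> float:
        return float(self.M_total.mean(axis=0)[1])

    @property
    def P_mean(self) -> float:
        return float(self.P_aer.mean())

    @property
    def P_peak(self) -> float:
        return float(self.P_aer.max())

    @property
    def F_mag_mean(self) -> float:
        return float(np.linalg.norm(self.F_total, axis=1).mean())

    @property
    def F_mag_peak(self) -> float:
        return float(np.linalg.norm(self.F_total, axis=1).max())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_s": self.times,
                "Fx_N": self.F_total[:, 0],
                "Fy_N": self.F_total[:, 1],
                "Fz_N": self.F_total[:, 2],
                "My_Nm": self.M_total[:, 1],
                "FLx_N": self.F_lift[:, 0],
                "FLz_N": self.F_lift[:, 2],
                "FDx_N": self.F_drag[:, 0],
                "FDz_N": self.F_drag[:, 2],
                "Frotx_N": self.F_rot[:, 0],
                "Frotz_N": self.F_rot[:, 2],
                "Fadmx_N": self.F_adm[:, 0],
                "Fadmz_N": self.F_adm[:, 2],
                "Finx_N": self.F_inertial[:, 0],
                "Finz_N": self.F_inertial[:, 2],
                "P_W": self.P_aer,
            }
        )
        return pd.concat([df, self.traces.reset_index(drop=True)], axis=1)

    def summary(self) -> dict:
        mg = self.config.weight
        r2 = self.config.scalars.r2
        return {
            "Fx_mean_N": self.Fx_mean,
            "Fz_mean_N": self.Fz_mean,
            "My_mean_Nm": self.My_mean,
            "Fx_mean_over_mg": self.Fx_mean / mg,
            "Fz_mean_over_mg": self.Fz_mean / mg,
            "My_mean_over_mgr2": self.My_mean / (mg * r2),
            "P_mean_W": self.P_mean,
            "P_peak_W": self.P_peak,
            "F_mag_mean_N": self.F_mag_mean,
            "F_mag_peak_N": self.F_mag_peak,
        }


_FLIP_Y = np.array([1.0, -1.0, 1.0])
_FLIP_XZ = np.array([-1.0, 1.0, -1.0])


def simulate_wingstroke(
    config: MothConfiguration,
    n_steps: int = 1000,
    n_strips: Optional[int] = None,
    explicit_both_wings: Optional[bool] = None,
) -> WingstrokeResult:
    """Simulate one full wingstroke on a uniform time grid over [0, 1/f).

    ``n_strips`` resamples the planform for reduced-fidelity evaluation
    (e.g. inside the trim search); the default uses the configured strips.
    With symmetric kinematics and no lateral wind the left wing is the
    exact y-mirror of the right, so its contribution is obtained by
    reflection; ``explicit_both_wings=True`` forces both kinematic
    chains to be evaluated (used to verify the mirror symmetry itself).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    morph = config.morph
    if n_strips is not None and n_strips != morph.n_strips:
        morph = morph.with_n_strips(n_strips)
    if explicit_both_wings is None:
        explicit_both_wings = config.ambient_wind[1] != 0.0
    f = config.f
    t = np.arange(n_steps) / (n_steps * f)
    ch = _chain(config, t)

    area_w = morph.chord * morph.dr  # (N,)
    S = area_w.sum()
    m_strip = morph.strip_mass

    F_L = np.zeros((n_steps, 3))
    F_D = np.zeros((n_steps, 3))
    F_R = np.zeros((n_steps, 3))
    F_A = np.zeros((n_steps, 3))
    M = np.zeros((n_steps, 3))
    F_in = np.zeros((n_steps, 3))
    P_d = np.zeros(n_steps)
    P_r = np.zeros(n_steps)
    P_a = np.zeros(n_steps)
    P_l = np.zeros(n_steps)
    traces = None

    sides = ("right", "left") if explicit_both_wings else ("right",)
    for side in sides:
        wa = _wing_arrays(config, ch, side, morph)
        fl, fd = wa["F_L"].sum(axis=1), wa["F_D"].sum(axis=1)
        fr, fa = wa["F_rot"].sum(axis=1), wa["F_adm"].sum(axis=1)
        Fw = wa["F_L"] + wa["F_D"] + wa["F_rot"] + wa["F_adm"]
        mw_ = np.cross(wa["pos"], Fw).sum(axis=1)
        fin = -(m_strip[None, :, None] * wa["acc"]).sum(axis=1)
        pd_ = np.einsum("tnc,tnc->t", wa["F_D"], wa["v_air"])
        pr_ = np.einsum("tnc,tnc->t", wa["F_rot"], wa["v_air"])
        pa_ = np.einsum("tnc,tnc->t", wa["F_adm"], wa["v_air"])
        pl_ = np.einsum("tnc,tnc->t", wa["F_L"], wa["v_air"])
        F_L += fl; F_D += fd; F_R += fr; F_A += fa
        M += mw_; F_in += fin
        P_d += pd_; P_r += pr_; P_a += pa_; P_l += pl_
        if not explicit_both_wings:
            # left wing by reflection: forces mirror in y, moments in x/z
            F_L += fl * _FLIP_Y; F_D += fd * _FLIP_Y
            F_R += fr * _FLIP_Y; F_A += fa * _FLIP_Y
            M += mw_ * _FLIP_XZ; F_in += fin * _FLIP_Y
            P_d += pd_; P_r += pr_; P_a += pa_; P_l += pl_
        if side == "right":
            traces = pd.DataFrame(
                {
                    "alpha_v_deg": np.rad2deg(wa["alpha_v"].mean(axis=1)),
                    "alpha_h_deg": np.rad2deg(wa["alpha_h"]),
                    "v_ms": wa["speed"].mean(axis=1),
                    "CL_w": (wa["CL"] * area_w[None, :]).sum(axis=1) / S,
                    "CD_w": (wa["CD"] * area_w[None, :]).sum(axis=1) / S,
                }
            )

    return WingstrokeResult(
        times=t,
        F_total=F_L + F_D + F_R + F_A,
        F_lift=F_L,
        F_drag=F_D,
        F_rot=F_R,
        F_adm=F_A,
        M_total=M,
        F_inertial=F_in,
        P_aer=P_d + P_r + P_a,
        P_drag=P_d,
        P_rot=P_r,
        P_adm=P_a,
        P_lift_residual=P_l,
        traces=traces,
        config=config,
    )
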