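"""Trim-equilibrium search over bounded wing/body kinematic parameters.

Steady forward flight requires the wingstroke-averaged fore-aft force to
vanish, the averaged vertical force to support the weight, and the
averaged pitching moment about the COM to vanish:

    Fx_mean = 0,   Fz_mean = m g,   My_mean = 0.

The trim residual is the normalized sum of squares

    G = (Fx_mean/mg)^2 + (Fz_mean/mg - 1)^2 + (My_mean/(mg r2))^2,

zero at perfect trim.  The search varies 14 parameters — wingbeat
frequency f, stroke-plane roll betar, the wingstroke mean and max-min
amplitude of the body pitch chi, stroke-plane angle beta, sweep phi,
feathering alpha and deviation theta waveforms, and the lift/drag
coefficient scalings kL and kD — inside per-species min/max bounds
measured across recorded wingstrokes.  Waveform shapes (harmonic ratios
and phases) stay fixed; only mean and amplitude are retargeted.

Minimization is derivative-free and bounded: each restart draws a
uniform point inside the box, localizes a minimum with a Nelder-Mead
simplex through a sinusoidal bound transform
(x = lo + (hi-lo)(sin z + 1)/2) on a reduced strip/time grid, and then
drives the residual to zero with a bounded Gauss-Newton pass
(finite-difference trust-region-reflective least squares on the
3-component residual vector), first at reduced then at full fidelity.
Because 3 equilibrium conditions constrain 14 parameters, zero-residual
minima form a high-dimensional set and different restarts land on
distinct solutions.  The reported G is always full-fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .aerodynamics import MothConfiguration, WingstrokeResult, simulate_wingstroke
from .kinematics import rescale_waveform, waveform_stats

__all__ = [
    "PARAM_NAMES",
    "TrimBounds",
    "TrimSolution",
    "SPECIES_BOUNDS",
    "SPECIES_TRIM_EXAMPLES",
    "trim_cost",
    "apply_parameters",
    "config_parameters",
    "search_trim",
]

PARAM_NAMES = (
    "f",
    "betar",
    "chi_mean",
    "chi_amp",
    "beta_mean",
    "beta_amp",
    "phi_mean",
    "phi_amp",
    "alpha_mean",
    "alpha_amp",
    "theta_mean",
    "theta_amp",
    "kL",
    "kD",
)

# Measured per-species search bounds (min, max) for the 14 trim
# parameters: f in Hz, angles in degrees, kL/kD dimensionless.  A sample
# characteristic trim solution accompanies each species for reference.
SPECIES_BOUNDS = {
    "automeris_io": {
        "f": (20.0, 24.0), "betar": (0.0, 4.0),
        "chi_mean": (2.0, 24.0), "chi_amp": (7.0, 17.0),
        "beta_mean": (36.0, 76.0), "beta_amp": (7.0, 18.0),
        "phi_mean": (5.0, 44.0), "phi_amp": (103.0, 149.0),
        "alpha_mean": (76.0, 88.0), "alpha_amp": (43.0, 71.0),
        "theta_mean": (-1.0, 1.0), "theta_amp": (13.0, 22.0),
        "kL": (0.5, 2.0), "kD": (0.6, 1.4),
    },
    "actias_luna": {
        "f": (13.0, 15.0), "betar": (-1.0, 2.0),
        "chi_mean": (-4.0, 27.0), "chi_amp": (20.0, 27.0),
        "beta_mean": (66.0, 82.0), "beta_amp": (20.0, 26.0),
        "phi_mean": (7.0, 17.0), "phi_amp": (124.0, 134.0),
        "alpha_mean": (78.0, 85.0), "alpha_amp": (32.0, 44.0),
        "theta_mean": (0.0, 1.0), "theta_amp": (21.0, 29.0),
        "kL": (0.5, 2.0), "kD": (0.6, 1.4),
    },
    "antheraea_polyphemus": {
        "f": (7.0, 13.0), "betar": (-5.0, 1.0),
        "chi_mean": (18.0, 21.0), "chi_amp": (37.0, 51.0),
        "beta_mean": (54.0, 68.0), "beta_amp": (32.0, 57.0),
        "phi_mean": (26.0, 38.0), "phi_amp": (119.0, 148.0),
        "alpha_mean": (82.0, 89.0), "alpha_amp": (45.0, 94.0),
        "theta_mean": (-1.0, 0.0), "theta_amp": (14.0, 38.0),
        "kL": (0.5, 2.0), "kD": (0.6, 1.4),
    },
    "hyalophora_euryalus": {
        "f": (12.0, 14.0), "betar": (-2.0, 1.0),
        "chi_mean": (34.0, 53.0), "chi_amp": (15.0, 25.0),
        "beta_mean": (22.0, 60.0), "beta_amp": (14.0, 28.0),
        "phi_mean": (5.0, 40.0), "phi_amp": (100.0, 127.0),
        "alpha_mean": (82.0, 93.0), "alpha_amp": (29.0, 51.0),
        "theta_mean": (-1.0, 1.0), "theta_amp": (12.0, 33.0),
        "kL": (0.5, 2.0), "kD": (0.6, 1.4),
    },
}

# One characteristic trim solution per species (reference data).
SPECIES_TRIM_EXAMPLES = {
    "automeris_io": dict(zip(PARAM_NAMES, (
        21.938, 1.461, 22.818, 12.768, 60.748, 7.592, 37.293, 127.09,
        82.674, 55.389, 0.322, 17.838, 1.705, 0.6))),
    "actias_luna": dict(zip(PARAM_NAMES, (
        13.011, -0.99, 26.946, 23.637, 68.876, 26.002, 16.424, 124.076,
        85.019, 43.99, 0.171, 21.019, 1.295, 0.6))),
    "antheraea_polyphemus": dict(zip(PARAM_NAMES, (
        8.872, -1.388, 20.016, 43.718, 64.007, 38.995, 33.461, 123.126,
        85.871, 45.67, -0.528, 30.98, 1.128, 0.609))),
    "hyalophora_euryalus": dict(zip(PARAM_NAMES, (
        12.329, -1.378, 48.363, 22.428, 44.245, 25.858, 31.608, 100.296,
        89.384, 36.175, -0.15, 20.715, 1.383, 0.612))),
}


@dataclass(frozen=True)
class TrimBounds:
    """Min/max box for the 14 trim-search parameters."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", np.asarray(self.lo, float))
        object.__setattr__(self, "hi", np.asarray(self.hi, float))
        if self.lo.shape != (14,) or self.hi.shape != (14,):
            raise ValueError("bounds must cover the 14 trim parameters")
        if np.any(self.lo > self.hi):
            raise ValueError("min bound exceeds max bound")

    @classmethod
    def from_dict(cls, d: dict) -> "TrimBounds":
        lo = np.array([d[n][0] for n in PARAM_NAMES])
        hi = np.array([d[n][1] for n in PARAM_NAMES])
        return cls(lo, hi)

    @classmethod
    def from_species(cls, species: str) -> "TrimBounds":
        if species not in SPECIES_BOUNDS:
            raise KeyError(
                f"unknown species '{species}'; known: {sorted(SPECIES_BOUNDS)}"
            )
        return cls.from_dict(SPECIES_BOUNDS[species])

    @property
    def range(self) -> np.ndarray:
        return self.hi - self.lo

    def contains(self, vec, relax: float = 0.0) -> bool:
        v = np.asarray(vec, float)
        pad = relax * self.range
        return bool(np.all(v >= self.lo - pad) and np.all(v <= self.hi + pad))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"parameter": PARAM_NAMES, "min": self.lo, "max": self.hi}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrimBounds":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"bounds file not found: {path}")
        df = pd.read_csv(path)
        for col in ("parameter", "min", "max"):
            if col not in df.columns:
                raise ValueError(f"bounds CSV {path} missing column '{col}'")
        d = {r.parameter: (r.min, r.max) for r in df.itertuples()}
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise ValueError(f"bounds CSV {path} missing parameters: {missing}")
        return cls.from_dict(d)


@dataclass
class TrimSolution:
    """One trim-equilibrium parameter vector with its residual."""

    params: np.ndarray  # (14,), order PARAM_NAMES
    G: float
    config: MothConfiguration
    n_cost_evals: int
    seed: int

    def as_dict(self) -> dict:
        d = dict(zip(PARAM_NAMES, map(float, self.params)))
        d["G"] = self.G
        d["seed"] = self.seed
        return d


def trim_cost(result: WingstrokeResult, mt: float, g: float, r2: float) -> float:
    """Normalized trim residual G of a simulated wingstroke."""
    if r2 <= 0:
        raise ValueError("r2 must be positive")
    mg = mt * g
    return float(
        (result.Fx_mean / mg) ** 2
        + (result.Fz_mean / mg - 1.0) ** 2
        + (result.My_mean / (mg * r2)) ** 2
    )


def config_parameters(config: MothConfiguration) -> np.ndarray:
    """The 14-vector of trim parameters describing a configuration."""
    wk, bk = config.wing_kin, config.body_kin
    vals = [config.f, wk.betar]
    for wf in (bk.chi, wk.beta, wk.phi, wk.alpha, wk.theta):
        m, a = waveform_stats(wf)
        vals += [m, a]
    vals += [config.kL, config.kD]
    return np.array(vals)


def apply_parameters(base: MothConfiguration, vec) -> MothConfiguration:
    """Retarget a configuration to a 14-parameter trim vector.

    Waveform shapes are preserved: each angle waveform is rescaled to the
    requested mean and max-min amplitude on a time base set by the new
    wingbeat frequency; the body-velocity waveforms keep their means and
    shapes with the time base rescaled; betar, kL and kD are replaced.
    """
    v = dict(zip(PARAM_NAMES, np.asarray(vec, float)))
    f = v["f"]
    wk, bk = base.wing_kin, base.body_kin

    def retarget(wf, mean, amp):
        return rescale_waveform(wf.with_frequency(f), mean, amp)

    wing = replace(
        wk,
        phi=retarget(wk.phi, v["phi_mean"], v["phi_amp"]),
        theta=retarget(wk.theta, v["theta_mean"], v["theta_amp"]),
        alpha=retarget(wk.alpha, v["alpha_mean"], v["alpha_amp"]),
        beta=retarget(wk.beta, v["beta_mean"], v["beta_amp"]),
        betar=v["betar"],
        f=f,
    )
    body = replace(
        bk,
        chi=retarget(bk.chi, v["chi_mean"], v["chi_amp"]),
        u=bk.u.with_frequency(f),
        w=bk.w.with_frequency(f),
    )
    return base.replace(wing_kin=wing, body_kin=body, kL=v["kL"], kD=v["kD"])


# ---------------------------------------------------------------------------
# Bounded Nelder-Mead multi-start search

def _to_box(z, lo, rng_w):
    return lo + rng_w * (np.sin(z) + 1.0) / 2.0

def _from_box(x, lo, rng_w):
    frac = np.clip((x - lo) / rng_w, 1e-12, 1.0 - 1e-12)
    return np.arcsin(2.0 * frac - 1.0)


def _distinct(vec, solutions, bounds: TrimBounds, threshold: float) -> bool:
    rng_w = np.where(bounds.range > 0, bounds.range, 1.0)
    for s in solutions:
        if np.max(np.abs(vec - s.params) / rng_w) <= threshold:
            return False
    return True


def search_trim(
    base: MothConfiguration,
    bounds: TrimBounds,
    n_solutions: int = 10,
    tol: float = 1e-6,
    seed: int = 0,
    max_restarts: int = 60,
    distinct_threshold: float = 0.02,
    search_fidelity: tuple[int, int] = (50, 200),
    full_fidelity: tuple[int, int] = (200, 1000),
    search_maxfev: int = 600,
    polish_maxfev: int = 8,
    on_exhausted: str = "raise",
) -> list[TrimSolution]:
    """Multi-start bounded simplex search for distinct trim solutions.

    Restart points are drawn uniformly inside the bounds from a seeded
    RNG; the whole search is deterministic given ``seed``.  Each accepted
    solution satisfies ``G <= tol`` at full fidelity and differs from
    every other accepted solution by more than ``distinct_threshold`` of
    the bound range in at least one parameter.

    If the restart budget runs out first, behaviour follows
    ``on_exhausted``: 'raise' (default) raises RuntimeError with the
    partial solution list attached as ``exc.solutions``; 'partial'
    returns the solutions found.
    """
    if n_solutions < 1:
        raise ValueError("n_solutions must be >= 1")
    rng = np.random.default_rng(seed)
    lo = bounds.lo
    rng_w = np.where(bounds.range > 0, bounds.range, 1.0)
    fixed = bounds.range == 0
    n_strips_s, n_steps_s = search_fidelity
    n_strips_f, n_steps_f = full_fidelity
    evals = [0]

    def residuals(vec, fid):
        evals[0] += 1
        cfg = apply_parameters(base, vec)
        n_strips, n_steps = fid
        res = simulate_wingstroke(cfg, n_steps=n_steps, n_strips=n_strips)
        mg = cfg.mt * cfg.g
        return np.array(
            [
                res.Fx_mean / mg,
                res.Fz_mean / mg - 1.0,
                res.My_mean / (mg * cfg.scalars.r2),
            ]
        )

    def cost(vec, fid):
        r = residuals(vec, fid)
        return float(r @ r)

    def cost_z(z, fid):
        x = _to_box(z, lo, rng_w)
        x[fixed] = lo[fixed]
        return cost(x, fid)

    def unit_to_box(y):
        x = lo + y * rng_w
        x[fixed] = lo[fixed]
        return x

    def gauss_newton(y0, fid, max_nfev):
        # bounded finite-difference least squares in unit-box coordinates
        sol = least_squares(
            lambda y: residuals(unit_to_box(y), fid),
            np.clip(y0, 1e-9, 1 - 1e-9),
            bounds=(0.0, 1.0),
            method="trf",
            diff_step=1e-6,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=max_nfev,
        )
        return sol.x

    solutions: list[TrimSolution] = []
    for _ in range(max_restarts):
        if len(solutions) >= n_solutions:
            break
        x0 = lo + rng.uniform(size=14) * bounds.range
        evals0 = evals[0]
        # reduced-fidelity simplex localization through the sin transform
        res = minimize(
            cost_z, _from_box(x0, lo, rng_w), args=((n_strips_s, n_steps_s),),
            method="Nelder-Mead",
            options=dict(maxfev=search_maxfev, xatol=1e-8, fatol=1e-12,
                         adaptive=True),
        )
        y = (_to_box(res.x, lo, rng_w) - lo) / rng_w
        # zero the residual vector up a fidelity ladder
        y = gauss_newton(y, (n_strips_s, n_steps_s), max_nfev=40)
        if cost(unit_to_box(y), (n_strips_s, n_steps_s)) > 1e6 * tol:
            continue  # stuck at a nonzero local minimum; next restart
        mid = (min(2 * n_strips_s, n_strips_f), min(2 * n_steps_s + n_steps_s, n_steps_f))
        y = gauss_newton(y, mid, max_nfev=12)
        y = gauss_newton(y, (n_strips_f, n_steps_f), max_nfev=polish_maxfev)
        x = unit_to_box(y)
        G_full = cost(x, (n_strips_f, n_steps_f))
        if G_full <= tol and _distinct(x, solutions, bounds, distinct_threshold):
            cfg = apply_parameters(base, x)
            if cfg.morph.n_strips != n_strips_f:
                cfg = cfg.replace(morph=cfg.morph.with_n_strips(n_strips_f))
            solutions.append(
                TrimSolution(
                    params=x, G=G_full, config=cfg,
                    n_cost_evals=evals[0] - evals0, seed=seed,
                )
            )

    if len(solutions) < n_solutions:
        if on_exhausted == "partial":
            return solutions
        err = RuntimeError(
            f"restart budget exhausted: found {len(solutions)} of "
            f"{n_solutions} distinct trim solutions"
        )
        err.solutions = solutions
        raise err
    return solutions


def solutions_to_csv(solutions: Sequence[TrimSolution], path) -> None:
    pd.DataFrame([s.as_dict() for s in solutions]).to_csv(path, index=False)


def solutions_from_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trim solutions file not found: {path}")
    df = pd.read_csv(path)
    missing = [n for n in PARAM_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"trim solutions CSV {path} missing columns: {missing}")
    return df
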