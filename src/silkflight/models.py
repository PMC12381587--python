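"""Body-kinematics model variants and flight-performance comparison.

The effect of body oscillations is isolated by recomputing the
aerodynamics of the same wing kinematics under altered body kinematics:

* model1  — the measured (or trimmed) time-varying body kinematics;
* model2  — no body oscillations: body pitch chi, stroke-plane angle
  beta and the body velocities u, w frozen at their wingstroke means;
* model3  — model1 body kinematics time-shifted by half a period
  (180 deg out of phase with the wing motion);
* model1a — body-speed (u, w) oscillations kept, chi (and beta, which
  oscillates with the body) flattened;
* model1b — chi (and beta) oscillations kept, u and w flattened.

Wing kinematic angles phi, theta, alpha are identical across variants.
Variants reuse the model1 (trimmed) parameters and are re-simulated, not
re-trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aerodynamics import MothConfiguration, WingstrokeResult, simulate_wingstroke
from .kinematics import phase_difference

__all__ = [
    "MODEL_TAGS",
    "PerformanceMetrics",
    "make_variant",
    "performance_metrics",
    "compare_variants",
    "oscillation_correlations",
]

MODEL_TAGS = ("model1", "model2", "model3", "model1a", "model1b")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Wingstroke-level aerodynamic performance numbers."""

    F_mag_mean: float  # N
    F_mag_peak: float  # N
    Fx_mean: float  # N
    Fz_mean: float  # N
    P_mean: float  # W
    P_peak: float  # W
    LD_ratio: float  # wingstroke-averaged CL over CD (area-weighted)
    phase_chi_phi_deg: Optional[float]  # None if chi has no fundamental


def make_variant(
    base: MothConfiguration, tag: str, flatten_beta_in_1a: bool = True
) -> MothConfiguration:
    """Build one body-kinematics variant of a configuration.

    The base is treated as model1.  ``flatten_beta_in_1a`` controls
    whether the stroke-plane angle, which oscillates with the body, is
    flattened together with chi in model1a.
    """
    if tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag '{tag}'; expected one of {MODEL_TAGS}")
    wk, bk = base.wing_kin, base.body_kin
    if tag == "model1":
        return base
    if tag == "model2":
        wing = replace(wk, beta=wk.beta.flattened())
        body = replace(bk, chi=bk.chi.flattened(), u=bk.u.flattened(), w=bk.w.flattened())
    elif tag == "model3":
        wing = replace(wk, beta=wk.beta.half_period_shifted())
        body = replace(
            bk,
            chi=bk.chi.half_period_shifted(),
            u=bk.u.half_period_shifted(),
            w=bk.w.half_period_shifted(),
        )
    elif tag == "model1a":
        wing = replace(wk, beta=wk.beta.flattened()) if flatten_beta_in_1a else wk
        body = replace(bk, chi=bk.chi.flattened())
    else:  # model1b
        wing = wk
        body = replace(bk, u=bk.u.flattened(), w=bk.w.flattened())
    return base.replace(wing_kin=wing, body_kin=body)


def performance_metrics(result: WingstrokeResult) -> PerformanceMetrics:
    """Summarize a simulated wingstroke.

    The lift-to-drag ratio is the ratio of wingstroke means of the
    area-weighted strip CL and CD traces carried by the result.
    """
    CD_mean = float(result.traces["CD_w"].mean())
    if CD_mean == 0.0:
        raise ZeroDivisionError("mean drag coefficient is zero; L/D undefined")
    CL_mean = float(result.traces["CL_w"].mean())
    cfg = result.config
    try:
        phase = phase_difference(cfg.body_kin.chi, cfg.wing_kin.phi)
    except ValueError:
        phase = None
    return PerformanceMetrics(
        F_mag_mean=result.F_mag_mean,
        F_mag_peak=result.F_mag_peak,
        Fx_mean=result.Fx_mean,
        Fz_mean=result.Fz_mean,
        P_mean=result.P_mean,
        P_peak=result.P_peak,
        LD_ratio=CL_mean / CD_mean,
        phase_chi_phi_deg=phase,
    )


def compare_variants(
    base: MothConfiguration,
    tags: Sequence[str] = ("model1", "model2", "model3"),
    n_steps: int = 1000,
    n_strips: Optional[int] = None,
    flatten_beta_in_1a: bool = True,
) -> pd.DataFrame:
    """Simulate model variants and tabulate metrics plus ratios vs model1.

    Returns one row per variant with the performance metrics and, for
    power and force magnitudes, the ratio to the model1 value.
    """
    if "model1" not in tags:
        raise ValueError("the comparison requires model1 as the reference")
    rows = {}
    for tag in tags:
        cfg = make_variant(base, tag, flatten_beta_in_1a=flatten_beta_in_1a)
        res = simulate_wingstroke(cfg, n_steps=n_steps, n_strips=n_strips)
        m = performance_metrics(res)
        rows[tag] = {
            "F_mag_mean_N": m.F_mag_mean,
            "F_mag_peak_N": m.F_mag_peak,
            "Fx_mean_N": m.Fx_mean,
            "Fz_mean_N": m.Fz_mean,
            "P_mean_W": m.P_mean,
            "P_peak_W": m.P_peak,
            "LD_ratio": m.LD_ratio,
            "phase_chi_phi_deg": m.phase_chi_phi_deg,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "variant"
    ref = df.loc["model1"]
    for col in ("P_mean_W", "P_peak_W", "F_mag_mean_N", "F_mag_peak_N"):
        df[col.replace("_W", "").replace("_N", "") + "_ratio_vs_model1"] = (
            df[col] / ref[col]
        )
    return df


def oscillation_correlations(species_summaries: Sequence[tuple]) -> dict:
    """Pearson correlations of body-pitch amplitude across species.

    ``species_summaries`` is a list of (chi_amplitude_deg, f_hz,
    Ws_m2_per_kg) tuples, one per species.  Returns correlation
    coefficients (with p-values) of chi amplitude against the wingbeat
    period 1/f, the wing loading Ws, and 1/(f*Ws).
    """
    arr = np.asarray(species_summaries, float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (chi_amp, f, Ws) summaries")
    chi_a, f, Ws = arr[:, 0], arr[:, 1], arr[:, 2]
    out = {}
    for name, x in (
        ("inv_f", 1.0 / f),
        ("Ws", Ws),
        ("inv_fWs", 1.0 / (f * Ws)),
    ):
        if np.ptp(x) == 0 or np.ptp(chi_a) == 0:
            raise ValueError("zero variance in a correlation input")
        r, p = sps.pearsonr(chi_a, x)
        out[f"r_vs_{name}"] = float(r)
        out[f"p_vs_{name}"] = float(p)
    return out
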