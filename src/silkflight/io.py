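"""Configuration serialization, kinematics tables and run manifests.

All on-disk formats are plain text: CSV ('.' decimal, comma separator,
header row) for tables and JSON for structured settings.  Angles are
degrees in every file; SI units elsewhere.  Every pipeline command writes
a manifest recording its inputs, seeds and settings so a run can be
replayed exactly.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aerodynamics import MothConfiguration, WingstrokeResult
from .kinematics import BodyKinematics, FourierWaveform, WingKinematics
from .morphology import WingMorphology

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "write_kinematics_table",
    "write_result",
    "write_manifest",
]


def _waveform_to_dict(wf: FourierWaveform) -> dict:
    return {"a0": wf.a0, "a": list(map(float, wf.a)), "b": list(map(float, wf.b)), "f": wf.f}


def _waveform_from_dict(d: dict) -> FourierWaveform:
    return FourierWaveform(a0=d["a0"], a=np.array(d["a"]), b=np.array(d["b"]), f=d["f"])


def config_to_dict(cfg: MothConfiguration) -> dict:
    m = cfg.morph
    return {
        "morphology": {
            "R_m": m.R,
            "strip_centres_m": list(map(float, m.strip_centres)),
            "chord_m": list(map(float, m.chord)),
            "pitch_axis_frac": list(map(float, m.pitch_axis_frac)),
            "wing_mass_kg": m.wing_mass,
            "hinge_offset_m": list(map(float, m.hinge_offset)),
        },
        "wing_kinematics": {
            "phi": _waveform_to_dict(cfg.wing_kin.phi),
            "theta": _waveform_to_dict(cfg.wing_kin.theta),
            "alpha": _waveform_to_dict(cfg.wing_kin.alpha),
            "beta": _waveform_to_dict(cfg.wing_kin.beta),
            "betar_deg": cfg.wing_kin.betar,
            "f_hz": cfg.wing_kin.f,
        },
        "body_kinematics": {
            "chi": _waveform_to_dict(cfg.body_kin.chi),
            "u": _waveform_to_dict(cfg.body_kin.u),
            "w": _waveform_to_dict(cfg.body_kin.w),
        },
        "total_mass_kg": cfg.mt,
        "kL": cfg.kL,
        "kD": cfg.kD,
        "rho_kg_m3": cfg.rho,
        "g_m_s2": cfg.g,
        "ambient_wind_m_s": list(map(float, cfg.ambient_wind)),
    }


def config_from_dict(d: dict) -> MothConfiguration:
    m = d["morphology"]
    r = np.array(m["strip_centres_m"])
    dr = float(np.mean(np.diff(r))) if r.size > 1 else m["R_m"]
    morph = WingMorphology(
        R=m["R_m"],
        strip_centres=r,
        dr=dr,
        chord=np.array(m["chord_m"]),
        pitch_axis_frac=np.array(m["pitch_axis_frac"]),
        wing_mass=m["wing_mass_kg"],
        hinge_offset=np.array(m["hinge_offset_m"]),
    )
    wkd = d["wing_kinematics"]
    wing = WingKinematics(
        phi=_waveform_from_dict(wkd["phi"]),
        theta=_waveform_from_dict(wkd["theta"]),
        alpha=_waveform_from_dict(wkd["alpha"]),
        beta=_waveform_from_dict(wkd["beta"]),
        betar=wkd["betar_deg"],
        f=wkd["f_hz"],
    )
    bkd = d["body_kinematics"]
    body = BodyKinematics(
        chi=_waveform_from_dict(bkd["chi"]),
        u=_waveform_from_dict(bkd["u"]),
        w=_waveform_from_dict(bkd["w"]),
    )
    return MothConfiguration(
        morph=morph,
        wing_kin=wing,
        body_kin=body,
        mt=d["total_mass_kg"],
        kL=d["kL"],
        kD=d["kD"],
        rho=d.get("rho_kg_m3", 1.225),
        g=d.get("g_m_s2", 9.81),
        ambient_wind=np.array(d.get("ambient_wind_m_s", [0.0, 0.0, 0.0])),
    )


def save_config(cfg: MothConfiguration, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=1))


def load_config(path) -> MothConfiguration:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"moth configuration file not found: {path}")
    try:
        d = json.loads(path.read_text())
        return config_from_dict(d)
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"malformed moth configuration {path}: {err}") from err


def write_kinematics_table(df: pd.DataFrame, path) -> None:
    cols = [
        "t_s", "stroke", "chi_deg", "beta_deg", "betar_deg",
        "phi_deg", "theta_deg", "alpha_deg", "u_ms", "w_ms",
    ]
    df[cols].to_csv(path, index=False)


def write_result(result: WingstrokeResult, csv_path) -> None:
    """Time series as CSV plus a JSON summary of averages and peaks."""
    csv_path = Path(csv_path)
    result.to_dataframe().to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(json.dumps(result.summary(), indent=1))


def write_manifest(out_dir, command: str, inputs: dict, settings: dict) -> Path:
    """Append a manifest entry for one pipeline command."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append(
        {
            "command": command,
            "inputs": {k: str(v) for k, v in inputs.items()},
            "settings": settings,
            "package_version": __version__,
            "python": platform.python_version(),
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        }
    )
    path.write_text(json.dumps(entries, indent=1))
    return path
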