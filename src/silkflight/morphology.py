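"""Wing planform representation and morphological scalars.

The aerodynamic model treats the combined fore+hindwing of one side as a
single rigid flat plate, discretized into spanwise-uniform chordwise strips
(midpoint rule).  From the discretized planform it derives the scalars the
model needs: single-wing area ``S``, the radius of the second moment of
area ``r2`` used to normalize pitching moments, and the wing loading
``Ws`` (total wing area of both wings divided by total mass, in m^2/kg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd

__all__ = [
    "WingMorphology",
    "MorphoScalars",
    "build_strips",
    "derive_scalars",
    "synthetic_wing",
    "read_morphology",
    "write_morphology",
]

#: conventional quarter-chord pitching-axis fraction, used when no
#: measured chordwise pitching-axis position is supplied.
DEFAULT_PITCH_AXIS_FRAC = 0.25


@dataclass(frozen=True)
class WingMorphology:
    """Span-discretized geometry of one (combined fore+hind) wing.

    Attributes
    ----------
    R : float
        Wing length (hinge to tip), m.
    strip_centres : ndarray, shape (n_strips,)
        Spanwise positions of strip centres, m.
    dr : float
        Uniform strip width ``R / n_strips``, m.
    chord : ndarray, shape (n_strips,)
        Chord length sampled at each strip centre, m.
    pitch_axis_frac : ndarray, shape (n_strips,)
        Chordwise position of the wing-pitching axis per strip,
        0 = leading edge, 1 = trailing edge (dimensionless).
    wing_mass : float
        Mass of one wing, kg.  Distributed over strips proportionally to
        strip area, ``m_i = wing_mass * c_i * dr / S``.
    hinge_offset : ndarray, shape (3,)
        Wing-hinge position relative to the body centre of mass,
        expressed in the body frame (x forward, y left-to-right mirror
        axis, z dorsal), m.  The right-wing hinge; the left is the
        y-mirror.
    """

    R: float
    strip_centres: np.ndarray
    dr: float
    chord: np.ndarray
    pitch_axis_frac: np.ndarray
    wing_mass: float = 0.0
    hinge_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "strip_centres", np.asarray(self.strip_centres, float))
        object.__setattr__(self, "chord", np.asarray(self.chord, float))
        object.__setattr__(
            self, "pitch_axis_frac", np.asarray(self.pitch_axis_frac, float)
        )
        object.__setattr__(self, "hinge_offset", np.asarray(self.hinge_offset, float))
        if np.any(self.chord < 0):
            raise ValueError("negative chord in wing profile")
        if np.any((self.pitch_axis_frac < 0) | (self.pitch_axis_frac > 1)):
            raise ValueError("pitch_axis_frac must lie in [0, 1]")

    @property
    def n_strips(self) -> int:
        return self.strip_centres.size

    @property
    def area(self) -> float:
        """Single-wing planform area S = sum(c_i * dr), m^2."""
        return float(np.sum(self.chord) * self.dr)

    @property
    def strip_mass(self) -> np.ndarray:
        """Per-strip mass m_i = wing_mass * c_i * dr / S, kg."""
        S = self.area
        if S == 0.0:
            return np.zeros_like(self.chord)
        return self.wing_mass * self.chord * self.dr / S

    def with_n_strips(self, n_strips: int) -> "WingMorphology":
        """Resample the planform at a different strip count.

        Chord and pitching-axis profiles are linearly interpolated from the
        current strip-centre samples (with end-value extrapolation), which
        is exact for profiles that were themselves sampled from a smooth
        generator at sufficient resolution.
        """
        if n_strips < 1:
            raise ValueError("n_strips must be >= 1")
        dr = self.R / n_strips
        r = (np.arange(n_strips) + 0.5) * dr
        chord = np.interp(r, self.strip_centres, self.chord)
        e = np.interp(r, self.strip_centres, self.pitch_axis_frac)
        return replace(
            self, strip_centres=r, dr=dr, chord=chord, pitch_axis_frac=e
        )


@dataclass(frozen=True)
class MorphoScalars:
    """Morphological scalars derived from one wing and the total mass.

    ``S`` is the single-wing area (m^2); ``r2 = sqrt(sum(c r^2 dr)/S)`` is
    the radius of the second moment of area (m); ``Ws = 2S/mt`` is the wing
    loading, total wing area of both wings over total mass (m^2/kg).
    """

    S: float
    r2: float
    Ws: float


def build_strips(
    chord_profile: Callable[[np.ndarray], np.ndarray],
    R: float,
    n_strips: int = 200,
    pitch_axis_frac: Union[float, Callable[[np.ndarray], np.ndarray]] = DEFAULT_PITCH_AXIS_FRAC,
    wing_mass: float = 0.0,
    hinge_offset=(0.0, 0.0, 0.0),
) -> WingMorphology:
    """Discretize a chord profile into spanwise strips.

    Parameters
    ----------
    chord_profile : callable
        Maps spanwise position r (m, vectorized) to chord length (m),
        nonnegative on [0, R].
    R : float
        Wing length, m.
    n_strips : int
        Number of chordwise strips (default 200).
    pitch_axis_frac : float or callable
        Chordwise pitching-axis fraction, constant or as a profile of r.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if n_strips < 1:
        raise ValueError("n_strips must be >= 1")
    dr = R / n_strips
    r = (np.arange(n_strips) + 0.5) * dr
    chord = np.asarray(chord_profile(r), float)
    if chord.shape != r.shape:
        chord = np.broadcast_to(chord, r.shape).copy()
    if np.any(chord < 0):
        raise ValueError("chord_profile returned a negative chord")
    if callable(pitch_axis_frac):
        e = np.asarray(pitch_axis_frac(r), float)
        e = np.broadcast_to(e, r.shape).copy()
    else:
        e = np.full_like(r, float(pitch_axis_frac))
    return WingMorphology(
        R=float(R),
        strip_centres=r,
        dr=dr,
        chord=chord,
        pitch_axis_frac=e,
        wing_mass=float(wing_mass),
        hinge_offset=np.asarray(hinge_offset, float),
    )


def derive_scalars(morph: WingMorphology, total_mass: float) -> MorphoScalars:
    """Compute S, r2 and wing loading Ws = 2S / total mass."""
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    S = morph.area
    if S > 0:
        r2 = float(
            np.sqrt(np.sum(morph.chord * morph.strip_centres**2) * morph.dr / S)
        )
    else:
        r2 = 0.0
    return MorphoScalars(S=S, r2=r2, Ws=2.0 * S / total_mass)


def synthetic_wing(
    shape_params: dict,
    R: float,
    seed: int = 0,
    n_strips: int = 200,
    pitch_axis_frac: Union[float, Callable] = DEFAULT_PITCH_AXIS_FRAC,
    wing_mass: float = 0.0,
    hinge_offset=(0.0, 0.0, 0.0),
) -> WingMorphology:
    """Generate a smooth moth-like planform from a Beta-function profile.

    The chord is ``c(r) = c0 * s(r/R) / max(s)`` with
    ``s(x) = x**(p-1) * (1-x)**(q-1)``, so the maximum chord equals ``c0``.
    ``p = q = 1`` gives a rectangular wing.  The construction is fully
    deterministic; ``seed`` is accepted for interface uniformity with the
    other generators and recorded nowhere.
    """
    c0 = float(shape_params["c0"])
    p = float(shape_params.get("p", 1.0))
    q = float(shape_params.get("q", 1.0))
    if c0 <= 0 or p <= 0 or q <= 0:
        raise ValueError("c0, p, q must be positive")

    def shape(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = x ** (p - 1.0) * (1.0 - x) ** (q - 1.0)
        return np.nan_to_num(s, nan=0.0, posinf=0.0)

    if p >= 1.0 and q >= 1.0:
        mode = (p - 1.0) / (p + q - 2.0) if p + q > 2.0 else 0.5
        smax = float(shape(np.array([mode]))[0]) or 1.0
    else:
        # profile unbounded at an edge; normalize by the largest sample
        xs = np.linspace(1e-6, 1 - 1e-6, 4096)
        smax = float(shape(xs).max())

    return build_strips(
        lambda r: c0 * shape(r / R) / smax,
        R=R,
        n_strips=n_strips,
        pitch_axis_frac=pitch_axis_frac,
        wing_mass=wing_mass,
        hinge_offset=hinge_offset,
    )


# ---------------------------------------------------------------------------
# I/O: strip table as CSV, scalar geometry as a JSON sidecar


def write_morphology(morph: WingMorphology, csv_path, total_mass: float | None = None) -> None:
    """Write the strip table (r_m, chord_m, pitch_axis_frac) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "r_m": morph.strip_centres,
            "chord_m": morph.chord,
            "pitch_axis_frac": morph.pitch_axis_frac,
        }
    ).to_csv(csv_path, index=False)
    sidecar = {
        "R_m": morph.R,
        "wing_mass_kg": morph.wing_mass,
        "hinge_offset_m": list(map(float, morph.hinge_offset)),
    }
    if total_mass is not None:
        sidecar["total_mass_kg"] = float(total_mass)
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_morphology(csv_path) -> tuple[WingMorphology, float | None]:
    """Read a strip table and sidecar; returns (morphology, total_mass or None)."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(f"morphology file not found: {csv_path}")
    df = pd.read_csv(csv_path)
    for col in ("r_m", "chord_m", "pitch_axis_frac"):
        if col not in df.columns:
            raise ValueError(f"morphology CSV {csv_path} missing column '{col}'")
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"morphology sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    r = df["r_m"].to_numpy()
    dr = float(np.mean(np.diff(r))) if r.size > 1 else float(meta["R_m"])
    morph = WingMorphology(
        R=float(meta["R_m"]),
        strip_centres=r,
        dr=dr,
        chord=df["chord_m"].to_numpy(),
        pitch_axis_frac=df["pitch_axis_frac"].to_numpy(),
        wing_mass=float(meta.get("wing_mass_kg", 0.0)),
        hinge_offset=np.asarray(meta.get("hinge_offset_m", [0.0, 0.0, 0.0]), float),
    )
    mt = meta.get("total_mass_kg")
    return morph, (float(mt) if mt is not None else None)
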