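"""Direction conventions, micromirror rotations and specular reflection.

Coordinate conventions
----------------------
The DMD backplane carries a right-handed frame (ê_x, ê_y, ê_z): ê_x and ê_y
run along the principal axes of the square mirror lattice, ê_z is the
backplane normal pointing away from the chip.  Directions are unit 3-vectors
in this frame; *incoming* beams travel toward the chip (z < 0), *outgoing*
beams away from it (z > 0).

Each micromirror reaches its two landed orientations ("+" and "−") by a
rotation R(m̂±, γ±) about an arbitrary unit axis m̂± through angle γ±.  The
mirror-fixed frame is ê_i = R ê_α (i = 1, 2, 3 for α = x, y, z); ê_3 is the
micromirror facet normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Direction",
    "MirrorGeometry",
    "build_rotation",
    "mirror_frame",
    "specular_direction",
    "inplane_angle_to_direction",
    "direction_to_inplane_angle",
    "load_preset",
    "save_preset",
    "list_presets",
    "TRP_NOMINAL",
    "TRP_FITTED",
    "CIP_NOMINAL",
]

MirrorState = Literal["+", "-"]

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class Direction:
    """A unit direction vector in the DMD backplane frame.

    Incoming directions (toward the chip) have ``z < 0``; outgoing ones
    ``z > 0``.  Construct through :meth:`incoming`, :meth:`outgoing` or
    :func:`inplane_angle_to_direction` so the z-component is consistent.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        n = self.x * self.x + self.y * self.y + self.z * self.z
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |v|^2 = {n!r}")

    @classmethod
    def incoming(cls, x: float, y: float) -> "Direction":
        """Incoming direction from transverse components, z = −√(1−x²−y²)."""
        return cls(x, y, -_z_from_xy(x, y))

    @classmethod
    def outgoing(cls, x: float, y: float) -> "Direction":
        """Outgoing direction from transverse components, z = +√(1−x²−y²)."""
        return cls(x, y, _z_from_xy(x, y))

    @classmethod
    def from_array(cls, v: np.ndarray) -> "Direction":
        v = np.asarray(v, dtype=float)
        return cls(float(v[0]), float(v[1]), float(v[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_incoming(self) -> bool:
        return self.z < 0

    def angle_to(self, other: "Direction") -> float:
        """Angle to another direction, in degrees."""
        c = float(np.clip(self.as_array() @ other.as_array(), -1.0, 1.0))
        return math.degrees(math.acos(c))

    def polar_angle(self) -> float:
        """Angle from the backplane normal (either side), degrees."""
        return math.degrees(math.acos(min(1.0, abs(self.z))))

    def __iter__(self) -> Iterator[float]:
        yield from (self.x, self.y, self.z)


def _z_from_xy(x: float, y: float) -> float:
    r2 = x * x + y * y
    if r2 > 1.0 + _UNIT_TOL:
        raise ValueError(f"transverse components exceed unit norm: x={x}, y={y}")
    return math.sqrt(max(0.0, 1.0 - r2))


def build_rotation(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a rotation of ``angle_deg`` about ``axis``.

    The axis must already be normalized; a non-unit axis raises rather than
    being silently rescaled, because the mirror kinematics are specified by a
    unit rotation axis.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    norm = float(np.linalg.norm(axis))
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"rotation axis must be unit-norm, got |axis| = {norm}")
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


@dataclass(frozen=True)
class MirrorGeometry:
    """Micromirror-array kinematics: lattice pitch plus per-state rotation.

    Parameters
    ----------
    pitch_um : float
        Mirror lattice period d in micrometres.
    axis_plus, axis_minus : tuple of float
        Unit rotation axes m̂± in backplane coordinates.
    gamma_plus_deg, gamma_minus_deg : float
        Rotation angles γ± in degrees, 0 < |γ| < 90.
    mirror_width_um : float, optional
        Reflective mirror width w used by the single-mirror diffraction
        envelope.  Defaults to ``0.92 * pitch_um`` (typical fill factor);
        only the envelope depends on it — all blaze-geometry results
        (angles, Δ_b) are insensitive to w.
    """

    pitch_um: float
    axis_plus: tuple[float, float, float]
    axis_minus: tuple[float, float, float]
    gamma_plus_deg: float
    gamma_minus_deg: float
    mirror_width_um: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if self.mirror_width_um is None:
            object.__setattr__(self, "mirror_width_um", 0.92 * self.pitch_um)
        if not 0 < self.mirror_width_um <= self.pitch_um:
            raise ValueError("mirror width must satisfy 0 < w <= pitch")
        for name in ("axis_plus", "axis_minus"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a unit vector")
            object.__setattr__(self, name, tuple(float(c) for c in ax))
        for g in (self.gamma_plus_deg, self.gamma_minus_deg):
            if not 0 < abs(g) < 90:
                raise ValueError("rotation angle must satisfy 0 < |gamma| < 90 deg")

    def axis(self, state: MirrorState) -> np.ndarray:
        _check_state(state)
        return np.asarray(self.axis_plus if state == "+" else self.axis_minus)

    def gamma_deg(self, state: MirrorState) -> float:
        _check_state(state)
        return self.gamma_plus_deg if state == "+" else self.gamma_minus_deg

    def rotation(self, state: MirrorState) -> np.ndarray:
        """R± = R(m̂±, γ±)."""
        return build_rotation(self.axis(state), self.gamma_deg(state))

    def mirror_normal(self, state: MirrorState) -> np.ndarray:
        """Micromirror facet normal ê_3 for the given landed state."""
        return self.rotation(state)[:, 2]

    def replace(self, **changes) -> "MirrorGeometry":
        return replace(self, **changes)


def _check_state(state: str) -> None:
    if state not in ("+", "-"):
        raise ValueError(f"mirror state must be '+' or '-', got {state!r}")


def mirror_frame(geom: MirrorGeometry, state: MirrorState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mirror-fixed orthonormal triad (ê_1, ê_2, ê_3) for one landed state.

    ê_i = R(m̂, γ) ê_α — the columns of the state's rotation matrix.  ê_3 is
    the micromirror facet normal.
    """
    R = geom.rotation(state)
    return R[:, 0], R[:, 1], R[:, 2]


def specular_direction(a: Direction, normal) -> Direction:
    """Mirror-law reflection of incoming ``a`` off a facet with ``normal``.

    Returns b = a − 2(a·n̂)n̂.  Raises if ``a`` is not incoming or if it
    illuminates the facet from behind (a·n̂ ≥ 0).
    """
    if not a.is_incoming:
        raise ValueError("specular_direction expects an incoming direction (z < 0)")
    n = np.asarray(normal, dtype=float)
    av = a.as_array()
    proj = float(av @ n)
    if proj >= 0:
        raise ValueError("illumination from behind the mirror facet (a . n >= 0)")
    return Direction.from_array(av - 2.0 * proj * n)


def inplane_angle_to_direction(
    theta_deg: float,
    plane: Literal["xz", "yz"] = "xz",
    sense: Literal["incoming", "outgoing"] = "incoming",
) -> Direction:
    """Direction at ``theta_deg`` from the backplane normal within one plane.

    For the xz plane an incoming beam maps to (sin θ, 0, −cos θ) and an
    outgoing one to (sin θ, 0, cos θ); the yz plane swaps x and y.
    """
    if not -90.0 < theta_deg < 90.0:
        raise ValueError("in-plane angle must lie strictly inside (-90, 90) degrees")
    if plane not in ("xz", "yz"):
        raise ValueError("plane must be 'xz' or 'yz'")
    if sense not in ("incoming", "outgoing"):
        raise ValueError("sense must be 'incoming' or 'outgoing'")
    s = math.sin(math.radians(theta_deg))
    c = math.cos(math.radians(theta_deg))
    cz = -c if sense == "incoming" else c
    return Direction(s, 0.0, cz) if plane == "xz" else Direction(0.0, s, cz)


def direction_to_inplane_angle(d: Direction, plane: Literal["xz", "yz"] = "xz") -> float:
    """Inverse of :func:`inplane_angle_to_direction` (degrees, signed)."""
    t = d.x if plane == "xz" else d.y
    return math.degrees(math.asin(max(-1.0, min(1.0, t))))


# ---------------------------------------------------------------------------
# Shipped presets
#
# The DLP4710 tilt-and-roll preset encodes the effective composite mirror
# rotation: the − state axis lies near −ê_y with a small out-of-plane (ê_z)
# component; the + state is the same geometry rotated 90° about ê_z.  The two
# free parameters (γ and the axis' out-of-plane tilt δ) are pinned by the
# characterized rotation-matrix ratio R₁₃⁻/R₂₃⁻ = 90.523 together with the
# device's blazed two-color diffraction solutions at 488/635 nm.
# ---------------------------------------------------------------------------

_TRP_GAMMA_DEG = 16.954783328140312
_TRP_AXIS_DELTA_DEG = 4.250471060533184
_COS_D = math.cos(math.radians(_TRP_AXIS_DELTA_DEG))
_SIN_D = math.sin(math.radians(_TRP_AXIS_DELTA_DEG))

TRP_NOMINAL = MirrorGeometry(
    pitch_um=5.4,
    axis_plus=(_COS_D, 0.0, _SIN_D),
    axis_minus=(0.0, -_COS_D, _SIN_D),
    gamma_plus_deg=_TRP_GAMMA_DEG,
    gamma_minus_deg=_TRP_GAMMA_DEG,
    label="TRP-DLP4710-nominal",
)

# Calibrated variant: rotation angle 17.7 deg, axis azimuth shifted 13 deg
# in the backplane (the characterized deviation from nominal kinematics).
_AZ = math.radians(13.0)
_FIT_AXIS = (
    math.sin(_AZ) * _COS_D,
    -math.cos(_AZ) * _COS_D,
    _SIN_D,
)

TRP_FITTED = MirrorGeometry(
    pitch_um=5.4,
    axis_plus=(-_FIT_AXIS[1], _FIT_AXIS[0], _FIT_AXIS[2]),
    axis_minus=_FIT_AXIS,
    gamma_plus_deg=17.7,
    gamma_minus_deg=17.7,
    label="TRP-DLP4710-fitted",
)

_SQ2 = 1.0 / math.sqrt(2.0)

CIP_NOMINAL = MirrorGeometry(
    pitch_um=7.56,
    axis_plus=(_SQ2, _SQ2, 0.0),
    axis_minus=(_SQ2, _SQ2, 0.0),
    gamma_plus_deg=12.0,
    gamma_minus_deg=-12.0,
    label="CIP-nominal",
)

_BUILTIN = {
    "TRP-DLP4710-nominal": TRP_NOMINAL,
    "TRP-DLP4710-fitted": TRP_FITTED,
    "CIP-nominal": CIP_NOMINAL,
}


def list_presets() -> list[str]:
    return sorted(_BUILTIN)


def load_preset(name_or_path: str | Path) -> MirrorGeometry:
    """Load a mirror geometry by built-in name or from a TOML preset file."""
    key = str(name_or_path)
    if key in _BUILTIN:
        return _BUILTIN[key]
    path = Path(name_or_path)
    if not path.exists():
        raise KeyError(
            f"unknown preset {key!r}; built-ins: {', '.join(list_presets())}"
        )
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return MirrorGeometry(
        pitch_um=float(cfg["pitch_um"]),
        mirror_width_um=float(cfg["width_um"]) if "width_um" in cfg else None,
        axis_plus=tuple(float(v) for v in cfg["axis_plus"]),
        axis_minus=tuple(float(v) for v in cfg["axis_minus"]),
        gamma_plus_deg=float(cfg["gamma_plus_deg"]),
        gamma_minus_deg=float(cfg["gamma_minus_deg"]),
        label=str(cfg.get("label", path.stem)),
    )


def save_preset(geom: MirrorGeometry, path: str | Path) -> Path:
    """Write a geometry as a TOML preset file readable by :func:`load_preset`."""
    path = Path(path)
    vec = lambda v: "[" + ", ".join(repr(float(c)) for c in v) + "]"  # noqa: E731
    text = (
        f'label = "{geom.label}"\n'
        f"pitch_um = {geom.pitch_um!r}\n"
        f"width_um = {geom.mirror_width_um!r}\n"
        f"axis_plus = {vec(geom.axis_plus)}\n"
        f"axis_minus = {vec(geom.axis_minus)}\n"
        f"gamma_plus_deg = {geom.gamma_plus_deg!r}\n"
        f"gamma_minus_deg = {geom.gamma_minus_deg!r}\n"
    )
    path.write_text(text)
    return path
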