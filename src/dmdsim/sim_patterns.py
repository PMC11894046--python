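"""Binary SIM grating generation, optical-train arithmetic and mask layout.

The DMD displays binary gratings; with coherent illumination each grating
adds satellite "suborders" around every mirror-lattice diffraction order at
offsets proportional to the pattern spatial frequency.  A Fourier mask in
the relay's Fourier plane blocks the main order and passes the two ±1
suborders, whose interference writes a sinusoidal fringe on the sample.
Note the fringe period is *half* the imaged grating period, because the two
passed suborders sit at ±ν around the (blocked) carrier.

Patterns are parameterized by a rational spatial-frequency vector
(cycles per mirror), which guarantees exact periodicity on the mirror
lattice and exact discrete Fourier coefficients over one period cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatternSpec",
    "OpticalTrain",
    "make_grating",
    "pattern_fourier_coefficient",
    "sample_plane_period",
    "dmd_period_for_sample_period",
    "fringe_period_nm",
    "grating_period_for_fringe",
    "frequency_enhancement",
    "effective_pixel_size",
    "nyquist_limit",
    "sampling_check",
    "fourier_mask_coordinates",
    "mask_to_svg",
    "acquisition_sequence",
    "make_pattern_set",
    "MaskHole",
]


def _as_fraction(x, max_den: int = 4096) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(max_den)


@dataclass(frozen=True)
class PatternSpec:
    """A binary DMD grating defined by a rational frequency vector.

    The mirror at lattice site (i, j) is placed in the used ("−") state when
    ``frac(f_x·i + f_y·j + phase_index/n_phases) < duty``.  ``frequency`` is
    in cycles per mirror; its rational components make the pattern exactly
    periodic with period ``(den(f_x), den(f_y))`` mirrors, so phase stepping
    by ``n_phases`` indices reproduces the bitmap exactly.
    """

    frequency: tuple[Fraction, Fraction]
    phase_index: int = 0
    n_phases: int = 3
    orientation_index: int = 0
    width: int = 1920
    height: int = 1080
    duty: float = 0.5

    def __post_init__(self) -> None:
        fx, fy = (_as_fraction(f) for f in self.frequency)
        object.__setattr__(self, "frequency", (fx, fy))
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must be in (0, 1)")
        if self.width < 1 or self.height < 1:
            raise ValueError("bitmap dimensions must be positive")
        if fx == 0 and fy == 0:
            # uniform pattern (all mirrors used); allowed, period cell 1x1
            pass

    @classmethod
    def from_period(
        cls,
        period_mirrors,
        orientation_deg: float = 0.0,
        max_denominator: int = 256,
        **kw,
    ) -> "PatternSpec":
        """Closest rational-frequency grating to a target period/orientation.

        The frequency vector (cosφ, sinφ)/P is rounded component-wise to
        rationals with denominator ≤ ``max_denominator``.
        """
        p = float(period_mirrors)
        if p <= 0:
            raise ValueError("period must be positive")
        phi = math.radians(orientation_deg)
        fx = Fraction(math.cos(phi) / p).limit_denominator(max_denominator)
        fy = Fraction(math.sin(phi) / p).limit_denominator(max_denominator)
        return cls(frequency=(fx, fy), **kw)

    @property
    def period_cell(self) -> tuple[int, int]:
        """Exact lattice period (columns, rows) of the bitmap."""
        fx, fy = self.frequency
        return (fx.denominator, fy.denominator)

    @property
    def period_mirrors(self) -> float:
        """Fundamental period along the grating normal, in mirrors."""
        fx, fy = self.frequency
        f = math.hypot(float(fx), float(fy))
        return math.inf if f == 0 else 1.0 / f

    @property
    def achieved_orientation_deg(self) -> float:
        fx, fy = self.frequency
        return math.degrees(math.atan2(float(fy), float(fx)))

    def with_phase(self, phase_index: int) -> "PatternSpec":
        return PatternSpec(
            frequency=self.frequency,
            phase_index=phase_index,
            n_phases=self.n_phases,
            orientation_index=self.orientation_index,
            width=self.width,
            height=self.height,
            duty=self.duty,
        )

    def pattern_id(self) -> str:
        fx, fy = self.frequency
        return f"o{self.orientation_index}_p{self.phase_index}_f{fx}_{fy}".replace("/", "d")


def _threshold_cell(spec: PatternSpec, width: int, height: int) -> np.ndarray:
    """Exact integer evaluation of frac(f_x i + f_y j + k/n) < duty.

    Rational arithmetic keeps lattice sites that fall exactly on the duty
    boundary classified consistently across phase steps (floating-point
    jitter there would break the phase-stepping translation symmetry).
    """
    fx, fy = spec.frequency
    L = math.lcm(fx.denominator, fy.denominator, spec.n_phases)
    va = fx.numerator * (L // fx.denominator)
    vb = fy.numerator * (L // fy.denominator)
    vc = spec.phase_index * (L // spec.n_phases)
    jj, ii = np.meshgrid(
        np.arange(height, dtype=np.int64), np.arange(width, dtype=np.int64), indexing="ij"
    )
    vals = (va * ii + vb * jj + vc) % L
    return vals < spec.duty * L


def make_grating(spec: PatternSpec) -> np.ndarray:
    """Render a PatternSpec to a strictly binary (bool) bitmap (H, W)."""
    return _threshold_cell(spec, spec.width, spec.height)


from functools import lru_cache


@lru_cache(maxsize=4096)
def pattern_fourier_coefficient(spec: PatternSpec, harmonic: int) -> complex:
    """Discrete Fourier coefficient of the bitmap at ``harmonic`` × frequency.

    Computed over one exact lattice period, so the result is free of
    windowing leakage: c_k = ⟨p(i,j)·exp(−2πi·k·(f_x i + f_y j))⟩.
    c_0 equals the duty cycle.  Coefficients depend only on the pattern (not
    the optics), so they are memoized.
    """
    px, py = spec.period_cell
    fx, fy = (float(f) for f in spec.frequency)
    jj, ii = np.meshgrid(np.arange(py), np.arange(px), indexing="ij")
    cell = _threshold_cell(spec, px, py)
    w = np.exp(-2j * np.pi * harmonic * (fx * ii + fy * jj))
    return complex((cell * w).mean())


# ---------------------------------------------------------------------------
# Optical train
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalTrain:
    """Relay + microscope imaging path between DMD, sample and camera.

    Defaults describe a 1:1 75 mm relay feeding a 200 mm tube lens and a
    60×/1.4 NA objective with a 6.5 μm-pixel camera.
    """

    relay_f1_mm: float = 75.0
    relay_f2_mm: float = 75.0
    tube_f_mm: float = 200.0
    objective_mag: float = 60.0
    objective_na: float = 1.4
    camera_pixel_um: float = 6.5
    post_mag: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "relay_f1_mm",
            "relay_f2_mm",
            "tube_f_mm",
            "objective_mag",
            "objective_na",
            "camera_pixel_um",
            "post_mag",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def relay_mag(self) -> float:
        return self.relay_f2_mm / self.relay_f1_mm

    @property
    def dmd_to_sample_demag(self) -> float:
        """Overall demagnification from DMD plane to sample plane."""
        return self.relay_mag / self.objective_mag


def sample_plane_period(dmd_period_mirrors: float, geom, train: OpticalTrain) -> float:
    """Sample-plane period (nm) of a feature with the given DMD period.

    Pure imaging arithmetic: period × pitch × relay magnification /
    objective magnification.
    """
    if dmd_period_mirrors <= 0:
        raise ValueError("period must be positive")
    return dmd_period_mirrors * geom.pitch_um * 1000.0 * train.dmd_to_sample_demag


def dmd_period_for_sample_period(sample_period_nm: float, geom, train: OpticalTrain) -> float:
    """Inverse of :func:`sample_plane_period` (mirrors)."""
    if sample_period_nm <= 0:
        raise ValueError("period must be positive")
    return sample_period_nm / (geom.pitch_um * 1000.0 * train.dmd_to_sample_demag)


def fringe_period_nm(dmd_period_mirrors: float, geom, train: OpticalTrain) -> float:
    """Sample-plane period of the two-beam interference fringe.

    The Fourier mask passes the ±1 suborders and blocks the carrier, so the
    fringe frequency is twice the imaged grating frequency.
    """
    return sample_plane_period(dmd_period_mirrors, geom, train) / 2.0


def grating_period_for_fringe(fringe_nm: float, geom, train: OpticalTrain) -> float:
    """DMD grating period (mirrors) producing the requested sample fringe."""
    return dmd_period_for_sample_period(2.0 * fringe_nm, geom, train)


def frequency_enhancement(excitation_nm: float, na: float, sample_period_nm: float) -> float:
    """Frequency-support gain of SIM over widefield for a fringe period p.

    (2NA/λ + 1/p) / (2NA/λ).  Raises if the fringe is finer than the
    illumination passband λ/(2NA) permits.
    """
    if excitation_nm <= 0 or na <= 0 or sample_period_nm <= 0:
        raise ValueError("inputs must be positive")
    abbe = excitation_nm / (2.0 * na)
    if sample_period_nm < abbe:
        raise ValueError(
            f"fringe period {sample_period_nm} nm is below the illumination "
            f"passband limit {abbe:.1f} nm"
        )
    return 1.0 + abbe / sample_period_nm


def effective_pixel_size(train: OpticalTrain) -> float:
    """Camera pixel pitch referred to the sample plane, in nm."""
    return train.camera_pixel_um * 1000.0 / (train.objective_mag * train.post_mag)


def nyquist_limit(emission_nm: float, na: float) -> float:
    """Maximal sampling distance λ/(4·NA) for the detection band, in nm."""
    if emission_nm <= 0 or na <= 0:
        raise ValueError("inputs must be positive")
    return emission_nm / (4.0 * na)


def sampling_check(train: OpticalTrain, emission_nm: float) -> bool:
    """True when the camera samples at or below the Nyquist distance."""
    return effective_pixel_size(train) <= nyquist_limit(emission_nm, train.objective_na)


# ---------------------------------------------------------------------------
# Fourier mask
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskHole:
    x_mm: float
    y_mm: float
    role: str  # "pass" or "block"
    label: str = ""
    warning: str = ""


def fourier_mask_coordinates(
    directions: Sequence[tuple[np.ndarray, str, str]],
    relay_f1_mm: float,
    axis_direction: np.ndarray | None = None,
    aperture_radius_mm: float = 12.7,
) -> list[MaskHole]:
    """Fourier-plane coordinates for a set of beam directions.

    ``directions`` is a sequence of (unit direction, role, label); ``role``
    is "block" for the main order and "pass" for the ±1 suborders.  The mask
    plane sits one focal length behind the first relay lens, whose optical
    axis is ``axis_direction`` (defaults to the first "block" entry, i.e.
    the main order).  Each beam lands at r = f₁·tan(angle to axis),
    decomposed along two transverse basis vectors.
    """
    if relay_f1_mm <= 0:
        raise ValueError("relay focal length must be positive")
    dirs = [(np.asarray(d, float) / np.linalg.norm(d), role, lab) for d, role, lab in directions]
    if axis_direction is None:
        blocks = [d for d, role, _ in dirs if role == "block"]
        axis = blocks[0] if blocks else dirs[0][0]
    else:
        axis = np.asarray(axis_direction, float)
        axis = axis / np.linalg.norm(axis)
    # transverse basis: u1 in the plane spanned by axis and x (or y if collinear)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u1 = seed - (seed @ axis) * axis
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)
    holes = []
    for d, role, lab in dirs:
        c = float(np.clip(d @ axis, -1.0, 1.0))
        t1, t2 = float(d @ u1), float(d @ u2)
        tr = math.hypot(t1, t2)
        if c <= 0:
            holes.append(MaskHole(math.nan, math.nan, role, lab, "beam does not reach the mask"))
            continue
        r = relay_f1_mm * (tr / c)  # f * tan(theta)
        if tr == 0.0:
            x = y = 0.0
        else:
            x, y = r * t1 / tr, r * t2 / tr
        warn = "" if r <= aperture_radius_mm else "outside lens aperture"
        holes.append(MaskHole(x, y, role, lab, warn))
    return holes


def mask_to_svg(holes: Iterable[MaskHole], path: str | Path, hole_radius_mm: float = 0.5,
                canvas_mm: float = 25.4) -> Path:
    """Write a printable mask template as SVG with true mm units."""
    path = Path(path)
    half = canvas_mm / 2.0
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{canvas_mm}mm" '
        f'height="{canvas_mm}mm" viewBox="{-half} {-half} {canvas_mm} {canvas_mm}">',
        f'<circle cx="0" cy="0" r="{half}" fill="none" stroke="black" stroke-width="0.1"/>',
    ]
    for h in holes:
        if math.isnan(h.x_mm):
            continue
        color = "red" if h.role == "block" else "black"
        fill = "red" if h.role == "block" else "none"
        parts.append(
            f'<circle cx="{h.x_mm:.4f}" cy="{h.y_mm:.4f}" r="{hole_radius_mm}" '
            f'fill="{fill}" stroke="{color}" stroke-width="0.1"><title>{h.label}</title></circle>'
        )
    parts.append("</svg>")
    path.write_text("\n".join(parts))
    return path


# ---------------------------------------------------------------------------
# Acquisition sequencing and pattern sets
# ---------------------------------------------------------------------------


def acquisition_sequence(
    n_orientations: int,
    n_phases: int,
    wavelengths_nm: Sequence[float],
    z_steps: int = 1,
    z_spacing_nm: float = 0.0,
) -> pd.DataFrame:
    """Deterministic lexicographic frame order (z, wavelength, orientation, phase)."""
    if n_orientations < 1 or n_phases < 1 or z_steps < 1 or len(wavelengths_nm) < 1:
        raise ValueError("all counts must be positive")
    rows = []
    for iz in range(z_steps):
        for lam in wavelengths_nm:
            for o in range(n_orientations):
                for p in range(n_phases):
                    rows.append(
                        {
                            "frame": len(rows),
                            "z_index": iz,
                            "z_nm": iz * z_spacing_nm,
                            "wavelength_nm": lam,
                            "orientation": o,
                            "phase": p,
                            "pattern_id": f"o{o}_p{p}",
                        }
                    )
    return pd.DataFrame(rows)


def make_pattern_set(
    period_mirrors,
    n_orientations: int = 3,
    n_phases: int = 3,
    width: int = 1920,
    height: int = 1080,
    duty: float = 0.5,
    max_denominator: int = 256,
) -> list[PatternSpec]:
    """Standard 2D-SIM pattern set: evenly spaced orientations × phase steps."""
    specs = []
    for o in range(n_orientations):
        phi = 180.0 * o / n_orientations
        for p in range(n_phases):
            specs.append(
                PatternSpec.from_period(
                    period_mirrors,
                    orientation_deg=phi,
                    max_denominator=max_denominator,
                    phase_index=p,
                    n_phases=n_phases,
                    orientation_index=o,
                    width=width,
                    height=height,
                    duty=duty,
                )
            )
    return specs


def write_bitmap(spec: PatternSpec, path: str | Path) -> Path:
    """Write the grating as a bit-exact 1-bit PNG or BMP (by extension)."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray(make_grating(spec)).convert("1", dither=Image.Dither.NONE)
    img.save(path)
    return path
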