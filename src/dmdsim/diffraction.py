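"""Mirror-lattice diffraction orders, blaze envelope and SIM contrast.

A coherent plane wave hitting the mirror lattice (pitch d) is diffracted
into orders (n_x, n_y) obeying the grating equations

    b_x − a_x = n_x λ/d,      b_y − a_y = n_y λ/d,

with the z-components fixed by unit norm (incoming z < 0, outgoing z > 0).
The relative intensity of each order is modulated by the single-mirror
(blaze) envelope, a product of squared sincs in the tilted mirror frame,
peaked exactly at the specular reflection off the mirror facet.  A displayed
binary pattern adds suborders around each main order at the pattern's
spatial frequency; the intensity imbalance η of the two ±1 suborders sets
the SIM modulation contrast m = 2η/(1+η²).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .geometry import Direction, MirrorGeometry, MirrorState, specular_direction
from .sim_patterns import PatternSpec, pattern_fourier_coefficient

__all__ = [
    "DiffractionOrder",
    "PlaneWave",
    "ContrastRecord",
    "SubOrder",
    "output_direction",
    "allowed_orders",
    "blaze_envelope_intensity",
    "blaze_violation_angle",
    "pattern_suborders",
    "suborders_to_frame",
    "beam_imbalance",
    "modulation_contrast",
]


class DiffractionOrder(NamedTuple):
    """Integer order indices (n_x, n_y) of the mirror-lattice grating."""

    n_x: int
    n_y: int

    def __str__(self) -> str:  # compact "(nx,ny)" for logs and filenames
        return f"({self.n_x},{self.n_y})"


@dataclass(frozen=True)
class PlaneWave:
    """A coherent plane wave: propagation direction plus vacuum wavelength."""

    direction: Direction
    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")


def _lam_over_d(wavelength_nm: float, pitch_um: float) -> float:
    if wavelength_nm <= 0 or pitch_um <= 0:
        raise ValueError("wavelength and pitch must be positive")
    return (wavelength_nm * 1e-3) / pitch_um


def output_direction(
    a: Direction,
    order: DiffractionOrder | tuple[int, int],
    wavelength_nm: float,
    pitch_um: float,
) -> Direction | None:
    """Outgoing direction of one diffraction order, or None if evanescent.

    Evanescent orders (|b_xy| > 1) are a value, not an error, so solvers can
    constrain against them.
    """
    if not a.is_incoming:
        raise ValueError("output_direction expects an incoming direction")
    nx, ny = order
    ld = _lam_over_d(wavelength_nm, pitch_um)
    bx = a.x + nx * ld
    by = a.y + ny * ld
    if bx * bx + by * by > 1.0:
        return None
    return Direction.outgoing(bx, by)


def allowed_orders(a: Direction, wavelength_nm: float, pitch_um: float) -> list[DiffractionOrder]:
    """All propagating diffraction orders for the given incidence."""
    if not a.is_incoming:
        raise ValueError("allowed_orders expects an incoming direction")
    ld = _lam_over_d(wavelength_nm, pitch_um)
    nmax = int(math.ceil(2.0 / ld)) + 1
    out = []
    for nx in range(-nmax, nmax + 1):
        for ny in range(-nmax, nmax + 1):
            bx = a.x + nx * ld
            by = a.y + ny * ld
            if bx * bx + by * by <= 1.0:
                out.append(DiffractionOrder(nx, ny))
    return sorted(out)


def blaze_envelope_intensity(
    a: Direction,
    b: Direction,
    geom: MirrorGeometry,
    state: MirrorState,
    wavelength_nm: float,
) -> float:
    """Single-mirror Fraunhofer envelope, normalized to 1 at its peak.

    Product over the two in-facet axes of sinc²[(w/λ)·(â−b̂)·ê_i]; the peak
    sits exactly at the specular reflection, where both projections vanish.
    """
    R = geom.rotation(state)
    u = a.as_array() - b.as_array()
    w_over_lam = geom.mirror_width_um / (wavelength_nm * 1e-3)
    s1 = np.sinc(w_over_lam * float(u @ R[:, 0]))  # np.sinc(x) = sin(pi x)/(pi x)
    s2 = np.sinc(w_over_lam * float(u @ R[:, 1]))
    return float((s1 * s2) ** 2)


def blaze_violation_angle(
    a: Direction,
    b: Direction,
    geom: MirrorGeometry,
    state: MirrorState,
) -> float:
    """Δ_b: angle (degrees) between ``b`` and the specular reflection of ``a``.

    Zero exactly when the blaze condition holds.
    """
    return b.angle_to(specular_direction(a, geom.mirror_normal(state)))


# ---------------------------------------------------------------------------
# Pattern suborders and SIM contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubOrder:
    """One pattern suborder around a main diffraction order."""

    harmonic: int
    freq_x: float  # cycles per mirror
    freq_y: float
    direction: Direction | None  # None when evanescent
    amplitude: float
    intensity: float


def pattern_suborders(
    pattern: PatternSpec | np.ndarray,
    a: Direction,
    wavelength_nm: float,
    geom: MirrorGeometry,
    state: MirrorState,
    main: DiffractionOrder | tuple[int, int],
    radius: int = 2,
) -> list[SubOrder]:
    """Suborders generated by a displayed pattern around one main order.

    The suborder at pattern frequency ν (cycles/mirror) leaves at
    b_xy = b_xy(main) + (λ/d)·ν with amplitude |c_ν|·√envelope, where c_ν is
    the pattern's discrete Fourier coefficient.  Harmonics k = −radius…radius
    of the pattern fundamental are returned; evanescent harmonics carry a
    None direction and zero intensity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    b_main = output_direction(a, main, wavelength_nm, geom.pitch_um)
    if b_main is None:
        raise ValueError(f"main order {tuple(main)} is evanescent for this incidence")
    if isinstance(pattern, PatternSpec):
        fx, fy = (float(f) for f in pattern.frequency)
        coef = lambda k: pattern_fourier_coefficient(pattern, k)  # noqa: E731
    else:
        bitmap = np.asarray(pattern)
        if bitmap.dtype != bool and not np.isin(bitmap, (0, 1)).all():
            raise ValueError("pattern bitmap must be strictly binary")
        fx, fy, coef = _bitmap_harmonics(bitmap.astype(float))
    ld = _lam_over_d(wavelength_nm, geom.pitch_um)
    out: list[SubOrder] = []
    for k in range(-radius, radius + 1):
        c = abs(coef(k))
        bx = b_main.x + ld * k * fx
        by = b_main.y + ld * k * fy
        if bx * bx + by * by > 1.0:
            out.append(SubOrder(k, k * fx, k * fy, None, 0.0, 0.0))
            continue
        b = Direction.outgoing(bx, by)
        amp = c * math.sqrt(blaze_envelope_intensity(a, b, geom, state, wavelength_nm))
        out.append(SubOrder(k, k * fx, k * fy, b, amp, amp * amp))
    return out


def _bitmap_harmonics(bitmap: np.ndarray):
    """Fundamental frequency and harmonic coefficients of a raw bitmap.

    Full-bitmap FFT; emits a warning because aperiodic patterns leak.  The
    fundamental is the strongest non-DC FFT peak.
    """
    warnings.warn(
        "pattern supplied as a raw bitmap: Fourier coefficients are computed "
        "over the full frame and will leak unless the pattern tiles it exactly",
        stacklevel=3,
    )
    F = np.fft.fft2(bitmap) / bitmap.size
    mag = np.abs(F).copy()
    mag[0, 0] = 0.0
    jy, jx = np.unravel_index(int(np.argmax(mag)), mag.shape)
    h, w = bitmap.shape
    fy = jy / h if jy <= h // 2 else (jy - h) / h
    fx = jx / w if jx <= w // 2 else (jx - w) / w

    def coef(k: int) -> complex:
        if k == 0:
            return complex(F[0, 0])
        iy = int(round(k * fy * h)) % h
        ix = int(round(k * fx * w)) % w
        return complex(F[iy, ix])

    return fx, fy, coef


def suborders_to_frame(
    suborders: Sequence[SubOrder], main: DiffractionOrder | tuple[int, int]
) -> pd.DataFrame:
    """Tabulate suborders with the CSV columns used by the exports."""
    nx, ny = main
    rows = []
    for s in suborders:
        rows.append(
            {
                "n_x": nx,
                "n_y": ny,
                "sub_x": s.freq_x,
                "sub_y": s.freq_y,
                "b_x": s.direction.x if s.direction else math.nan,
                "b_y": s.direction.y if s.direction else math.nan,
                "b_z": s.direction.z if s.direction else math.nan,
                "envelope": (s.amplitude ** 2) if s.direction else 0.0,
                "intensity": s.intensity,
            }
        )
    return pd.DataFrame(rows)


def beam_imbalance(intensity_plus: float, intensity_minus: float) -> float:
    """η = min(I₊, I₋)/max(I₊, I₋), in [0, 1]; symmetric in its arguments."""
    if intensity_plus < 0 or intensity_minus < 0:
        raise ValueError("intensities must be non-negative")
    hi = max(intensity_plus, intensity_minus)
    if hi == 0:
        raise ValueError("both intensities are zero; imbalance undefined")
    return min(intensity_plus, intensity_minus) / hi


def modulation_contrast(eta: float) -> float:
    """SIM fringe contrast m = 2η/(1+η²) of two interfering beams.

    Strictly increasing on [0, 1] with m(1) = 1; equal beams give perfect
    contrast, a missing beam gives none.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    return 2.0 * eta / (1.0 + eta * eta)


@dataclass(frozen=True)
class ContrastRecord:
    """±1 suborder intensities with the derived imbalance and contrast."""

    intensity_plus: float
    intensity_minus: float
    eta: float
    m: float
    wavelength_nm: float = 0.0

    @classmethod
    def from_intensities(
        cls, intensity_plus: float, intensity_minus: float, wavelength_nm: float = 0.0
    ) -> "ContrastRecord":
        eta = beam_imbalance(intensity_plus, intensity_minus)
        return cls(intensity_plus, intensity_minus, eta, modulation_contrast(eta), wavelength_nm)
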