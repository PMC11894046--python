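"""Blaze-condition optimization under the mirror-lattice diffraction constraints.

For a chosen diffraction order, wavelength and mirror state, the blaze
violation is scored by the cost

    C(â, b̂) = (b₁ − a₁)² + (b₂ − a₂)²

(the in-facet transverse mismatch between the diffracted output and a true
specular reflection), minimized subject to the two grating equations via
Lagrange multipliers.

Structure of the solution set.  Writing ν = (n_x λ/d, n_y λ/d), the
constraints give b_xy = a_xy + ν, and in the mirror frame

    b_i − a_i = K_i + R_{3i}·Δz,   K_i = ν_x R_{1i} + ν_y R_{2i},

where Δz = b_z − a_z is the only quantity that still depends on the free
transverse components.  The cost is therefore a 1-D parabola in Δz with
closed-form minimizer Δz*; the stationary set of the Lagrange system is the
*level curve* Δz(a_xy) = Δz*, which explains why optimal directions form a
one-parameter family (closed curves in output-direction space).  When Δz*
exceeds the feasible maximum 2√(1 − |ν|²/4) the family collapses to the
single symmetric point a_xy = −ν/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diffraction import (
    ContrastRecord,
    DiffractionOrder,
    blaze_violation_angle,
    output_direction,
    pattern_suborders,
)
from .geometry import Direction, MirrorGeometry, MirrorState
from .sim_patterns import OpticalTrain, PatternSpec, grating_period_for_fringe

__all__ = [
    "BlazeSolution",
    "ExactSolutionReport",
    "cost",
    "exact_solution_condition",
    "solve_family",
    "solve_inplane",
    "two_color_compromise",
    "family_to_frame",
    "InfeasibleOrderError",
]

# Sample fringe periods (nm) used by the shipped two-color design.
DESIGN_FRINGE_NM = {488.0: 310.0, 635.0: 425.0}


class InfeasibleOrderError(ValueError):
    """No propagating input/output pair exists for the requested order."""


@dataclass(frozen=True)
class BlazeSolution:
    """One optimal input/output direction pair for a diffraction order."""

    a: Direction
    b: Direction
    order: DiffractionOrder
    wavelength_nm: float
    state: MirrorState
    cost: float
    delta_b_deg: float
    family_parameter: float = 0.0
    multipliers: tuple[float, float] = (0.0, 0.0)
    degenerate: bool = False
    global_minimum: bool = True

    @property
    def incidence_deg(self) -> float:
        """Incidence angle from the backplane normal, degrees."""
        return self.a.polar_angle()

    @property
    def output_deg(self) -> float:
        """Diffraction angle from the backplane normal, degrees."""
        return self.b.polar_angle()

    def to_record(self) -> dict:
        return {
            "state": self.state,
            "n_x": self.order.n_x,
            "n_y": self.order.n_y,
            "wavelength_nm": self.wavelength_nm,
            "a_x": self.a.x,
            "a_y": self.a.y,
            "a_z": self.a.z,
            "b_x": self.b.x,
            "b_y": self.b.y,
            "b_z": self.b.z,
            "incidence_deg": self.incidence_deg,
            "output_deg": self.output_deg,
            "delta_b_deg": self.delta_b_deg,
            "cost": self.cost,
            "family_parameter": self.family_parameter,
            "degenerate": self.degenerate,
        }


def cost(a: Direction, b: Direction, geom: MirrorGeometry, state: MirrorState) -> float:
    """Blaze-violation cost: squared in-facet mismatch between b̂ and â."""
    R = geom.rotation(state)
    u = b.as_array() - a.as_array()
    return float((u @ R[:, 0]) ** 2 + (u @ R[:, 1]) ** 2)


# ---------------------------------------------------------------------------
# Exact-solution condition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExactSolutionReport:
    """Whether the over-determined blaze+diffraction system has exact solutions."""

    ratio: float  # R13/R23 (inf when R23 = 0, nan when both vanish)
    orders: tuple[DiffractionOrder, ...]
    note: str = ""

    @property
    def has_exact(self) -> bool:
        return len(self.orders) > 0


def exact_solution_condition(
    geom: MirrorGeometry,
    state: MirrorState,
    max_order: int = 6,
    tol: float = 1e-9,
) -> ExactSolutionReport:
    """Low-order diffraction orders admitting an exactly blazed geometry.

    Exact solutions require n_x/n_y = R₁₃/R₂₃, so they exist only when that
    ratio is (numerically) a rational with numerator and denominator within
    ``max_order``.  A flat mirror (both elements zero) is blazed only in the
    (0, 0) order; R₂₃ = 0 reports an infinite ratio and flags the (n, 0)
    orders as the approximate in-plane family.
    """
    R = geom.rotation(state)
    r13, r23 = float(R[0, 2]), float(R[1, 2])
    if abs(r13) < tol and abs(r23) < tol:
        return ExactSolutionReport(math.nan, (DiffractionOrder(0, 0),), "flat mirror: specular only")
    if abs(r23) < tol:
        orders = tuple(DiffractionOrder(n, 0) for n in range(-max_order, max_order + 1) if n)
        return ExactSolutionReport(math.inf, orders, "R23 = 0: (n, 0) orders exactly blazed")
    ratio = r13 / r23
    frac = Fraction(ratio).limit_denominator(max_order)
    if frac != 0 and abs(frac.numerator) <= max_order and abs(float(frac) - ratio) <= tol:
        p, q = frac.numerator, frac.denominator
        orders = tuple(
            DiffractionOrder(k * p, k * q)
            for k in range(-max_order, max_order + 1)
            if k and abs(k * p) <= max_order and abs(k * q) <= max_order
        )
        return ExactSolutionReport(ratio, orders)
    return ExactSolutionReport(ratio, (), "no low-order rational ratio: no exact solutions")


# ---------------------------------------------------------------------------
# Family geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _FamilyCore:
    nu: np.ndarray  # (nu_x, nu_y)
    K1: float
    K2: float
    R: np.ndarray
    dz_star: float  # unconstrained cost minimizer in dz
    dz_max: float  # feasible maximum of dz
    degenerate: bool

    @property
    def dz_opt(self) -> float:
        return min(self.dz_star, self.dz_max)


def _family_core(
    order: DiffractionOrder | tuple[int, int],
    wavelength_nm: float,
    geom: MirrorGeometry,
    state: MirrorState,
    collapse_tol: float = 1e-4,
) -> _FamilyCore:
    nx, ny = order
    ld = (wavelength_nm * 1e-3) / geom.pitch_um
    nu = np.array([nx * ld, ny * ld])
    if np.linalg.norm(nu) >= 2.0:
        raise InfeasibleOrderError(
            f"order ({nx},{ny}) at {wavelength_nm} nm has no propagating pair"
        )
    R = geom.rotation(state)
    K1 = float(nu @ R[:2, 0])
    K2 = float(nu @ R[:2, 1])
    R31, R32 = float(R[2, 0]), float(R[2, 1])
    dz_star = -(K1 * R31 + K2 * R32) / (R31 * R31 + R32 * R32)
    dz_max = 2.0 * math.sqrt(1.0 - float(nu @ nu) / 4.0)
    return _FamilyCore(nu, K1, K2, R, dz_star, dz_max, dz_star >= dz_max - collapse_tol)


def _dz(a_xy: np.ndarray, nu: np.ndarray) -> float:
    b_xy = a_xy + nu
    ra = float(a_xy @ a_xy)
    rb = float(b_xy @ b_xy)
    if ra > 1.0 or rb > 1.0:
        return -math.inf
    return math.sqrt(1.0 - rb) + math.sqrt(1.0 - ra)


def _solution_at(
    a_xy: np.ndarray,
    core: _FamilyCore,
    order: DiffractionOrder,
    wavelength_nm: float,
    geom: MirrorGeometry,
    state: MirrorState,
    family_parameter: float = 0.0,
    degenerate: bool = False,
) -> BlazeSolution:
    a = Direction.incoming(float(a_xy[0]), float(a_xy[1]))
    b_xy = a_xy + core.nu
    b = Direction.outgoing(float(b_xy[0]), float(b_xy[1]))
    c = cost(a, b, geom, state)
    return BlazeSolution(
        a=a,
        b=b,
        order=DiffractionOrder(*order),
        wavelength_nm=wavelength_nm,
        state=state,
        cost=c,
        delta_b_deg=blaze_violation_angle(a, b, geom, state),
        family_parameter=family_parameter,
        multipliers=_multipliers(a, b, geom, state),
        degenerate=degenerate,
    )


def _multipliers(a: Direction, b: Direction, geom: MirrorGeometry, state: MirrorState) -> tuple[float, float]:
    """Lagrange multipliers (α, β) = −∂C/∂(b_x, b_y) at a stationary point."""
    R = geom.rotation(state)
    u = b.as_array() - a.as_array()
    d1, d2 = float(u @ R[:, 0]), float(u @ R[:, 1])
    # d b_i / d b_x = R_1i - R_3i * b_x/b_z  (b_z > 0)
    gbx = 2 * d1 * (R[0, 0] - R[2, 0] * b.x / b.z) + 2 * d2 * (R[0, 1] - R[2, 1] * b.x / b.z)
    gby = 2 * d1 * (R[1, 0] - R[2, 0] * b.y / b.z) + 2 * d2 * (R[1, 1] - R[2, 1] * b.y / b.z)
    return (-float(gbx), -float(gby))


def solve_family(
    order: DiffractionOrder | tuple[int, int],
    wavelength_nm: float,
    geom: MirrorGeometry,
    state: MirrorState,
    n_points: int = 360,
) -> list[BlazeSolution]:
    """Trace the one-parameter family of cost-optimal direction pairs.

    Returns the level curve Δz = Δz* as an ordered list of solutions with an
    arc-length ``family_parameter`` normalized to [0, 1); a collapsed family
    returns a single degenerate point.  Every returned point satisfies the
    diffraction constraints exactly and the Lagrange stationarity conditions
    to round-off.
    """
    if n_points < 1:
        raise ValueError("n_points must be positive")
    core = _family_core(order, wavelength_nm, geom, state)
    center = -core.nu / 2.0
    if core.degenerate or n_points == 1:
        return [
            _solution_at(center, core, DiffractionOrder(*order), wavelength_nm, geom, state,
                         degenerate=core.degenerate)
        ]
    pts = []
    for theta in np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False):
        u = np.array([math.cos(theta), math.sin(theta)])
        r_max = _max_radius(center, u, core.nu)
        g = lambda r: _dz(center + r * u, core.nu) - core.dz_star  # noqa: E731
        if g(r_max) > 0:
            # level not reached before the propagation boundary: clip there
            pts.append(center + r_max * u)
            continue
        pts.append(center + brentq(g, 0.0, r_max, xtol=1e-14) * u)
    # arc-length parameterization
    arr = np.array(pts)
    seg = np.linalg.norm(np.diff(np.vstack([arr, arr[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    total = float(seg.sum())
    return [
        _solution_at(p, core, DiffractionOrder(*order), wavelength_nm, geom, state,
                     family_parameter=float(si / total) if total > 0 else 0.0)
        for p, si in zip(arr, s)
    ]


def _max_radius(center: np.ndarray, u: np.ndarray, nu: np.ndarray) -> float:
    """Distance from center along u to the edge of the propagating domain."""

    def hit(c: np.ndarray) -> float:
        # solve |c + r u| = 1 for r > 0
        b = float(c @ u)
        disc = b * b - (float(c @ c) - 1.0)
        return -b + math.sqrt(max(0.0, disc))

    return min(hit(center), hit(center + nu)) * (1.0 - 1e-12)


def solve_inplane(
    order: DiffractionOrder | tuple[int, int],
    wavelength_nm: float,
    geom: MirrorGeometry,
    state: MirrorState,
    plane: Literal["xz", "yz"] | None = None,
) -> BlazeSolution:
    """The family point whose directions stay in a single incidence plane.

    For the − state this is the xz plane with orders (n, 0); for the + state
    the yz plane with orders (0, n).  Of the two in-plane crossings of the
    family curve, the one with incoming and outgoing beams on the positive-
    component side is returned (the experimentally used branch).
    """
    nx, ny = order
    if plane is None:
        plane = "xz" if state == "-" else "yz"
    if plane == "xz" and ny != 0:
        raise ValueError("in-plane xz solutions require an (n, 0) order")
    if plane == "yz" and nx != 0:
        raise ValueError("in-plane yz solutions require a (0, n) order")
    core = _family_core(order, wavelength_nm, geom, state)
    axis = 0 if plane == "xz" else 1
    nu1 = float(core.nu[axis])
    center = -nu1 / 2.0
    if core.degenerate:
        a_xy = np.zeros(2)
        a_xy[axis] = center
        return _solution_at(a_xy, core, DiffractionOrder(*order), wavelength_nm, geom, state,
                            degenerate=True)

    def g(t: float) -> float:
        a_xy = np.zeros(2)
        a_xy[axis] = t
        return _dz(a_xy, core.nu) - core.dz_star

    hi = min(1.0, 1.0 - nu1) * (1.0 - 1e-12)  # t <= 1 and t + nu <= 1
    if g(hi) > 0:
        raise InfeasibleOrderError(
            f"no in-plane family crossing for order ({nx},{ny}) at {wavelength_nm} nm"
        )
    t = brentq(g, center, hi, xtol=1e-14)
    a_xy = np.zeros(2)
    a_xy[axis] = t
    return _solution_at(a_xy, core, DiffractionOrder(*order), wavelength_nm, geom, state)


# ---------------------------------------------------------------------------
# Two-color compromise
# ---------------------------------------------------------------------------


def two_color_compromise(
    anchor: BlazeSolution,
    second_wavelength_nm: float,
    second_order: DiffractionOrder | tuple[int, int],
    geom: MirrorGeometry,
    train: OpticalTrain | None = None,
    fringe_nm: dict[float, float] | None = None,
    contrast: bool = True,
    suborder_orientation_deg: float = 0.0,
) -> tuple[BlazeSolution, dict[float, ContrastRecord]]:
    """Realign a second color onto the anchor's output direction.

    The second wavelength's incidence follows from the grating equations
    with b̂ held fixed at the anchor output; its blaze violation generally
    grows.  When ``contrast`` is requested, the predicted SIM contrast per
    color is computed from the ±1 suborders of the design gratings (fringe
    periods per wavelength from ``fringe_nm``, default 310/425 nm at 488/635;
    other wavelengths use the fringe giving a 1.55× frequency support).
    """
    train = train or OpticalTrain()
    fringe_nm = {**DESIGN_FRINGE_NM, **(fringe_nm or {})}
    nx, ny = second_order
    ld2 = (second_wavelength_nm * 1e-3) / geom.pitch_um
    ax = anchor.b.x - nx * ld2
    ay = anchor.b.y - ny * ld2
    if ax * ax + ay * ay > 1.0:
        raise InfeasibleOrderError(
            f"no physical incidence: order ({nx},{ny}) at {second_wavelength_nm} nm "
            "cannot reach the anchor output"
        )
    a2 = Direction.incoming(ax, ay)
    # the realigned geometry is fully determined; cost/delta_b are diagnostics
    geom_state = anchor.state
    sol2 = BlazeSolution(
        a=a2,
        b=anchor.b,
        order=DiffractionOrder(nx, ny),
        wavelength_nm=second_wavelength_nm,
        state=geom_state,
        cost=cost(a2, anchor.b, geom, geom_state),
        delta_b_deg=blaze_violation_angle(a2, anchor.b, geom, geom_state),
    )
    records: dict[float, ContrastRecord] = {}
    if contrast:
        for sol in (anchor, sol2):
            lam = sol.wavelength_nm
            fr = fringe_nm.get(lam, lam / (1.1 * train.objective_na))
            period = grating_period_for_fringe(fr, geom, train)
            spec = PatternSpec.from_period(period, orientation_deg=suborder_orientation_deg)
            subs = pattern_suborders(spec, sol.a, lam, geom, geom_state, sol.order, radius=1)
            by_k = {s.harmonic: s.intensity for s in subs}
            records[lam] = ContrastRecord.from_intensities(by_k[+1], by_k[-1], lam)
    return sol2, records


def family_to_frame(solutions: list[BlazeSolution]) -> pd.DataFrame:
    """Atlas rows (b_x, b_y, delta_b, order, wavelength, state, ...)."""
    return pd.DataFrame([s.to_record() for s in solutions])
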