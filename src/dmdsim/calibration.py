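"""Mirror-parameter calibration from displayed-pattern suborder intensities.

The true mirror rotation of a device usually deviates from its nominal
kinematics.  Displaying a series of gratings (several orientations and
periods) and recording the relative intensities of their diffraction
suborders constrains the rotation axis (2 d.o.f.) and angle (1 d.o.f.),
because the blaze envelope sampled by each suborder moves with the mirror
facet.  This module provides the forward simulator for such measurements
(with configurable multiplicative noise) and a least-squares model that
recovers the parameters, statsmodels-style: a model object built from a
dataset whose ``fit()`` returns a results object with estimates,
linearized confidence half-widths and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .blaze_solver import solve_inplane, two_color_compromise
from .diffraction import (
    ContrastRecord,
    DiffractionOrder,
    PlaneWave,
    blaze_envelope_intensity,
    output_direction,
    pattern_suborders,
)
from .geometry import Direction, MirrorGeometry, MirrorState, build_rotation
from .sim_patterns import OpticalTrain, PatternSpec

__all__ = [
    "CalibrationDataset",
    "simulate_calibration",
    "MirrorCalibrationModel",
    "MirrorCalibrationResults",
    "fit_mirror_params",
    "predicted_contrast_from_fit",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the calibration fit fails; carries the best point found."""

    def __init__(self, message: str, best: "MirrorCalibrationResults | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class CalibrationDataset:
    """Suborder-intensity measurements for a set of displayed patterns.

    ``records`` has one row per (pattern, suborder harmonic) with the
    measured relative intensity.  ``patterns`` keeps the full pattern
    specifications so the forward model can be re-evaluated.  For synthetic
    data the generating geometry is retained in ``true_geometry``.
    """

    patterns: list[PatternSpec]
    records: pd.DataFrame  # columns: pattern_index, harmonic, intensity
    illumination: PlaneWave
    main_order: DiffractionOrder
    state: MirrorState = "-"
    noise_sigma: float = 0.0
    seed: int | None = None
    true_geometry: MirrorGeometry | None = None

    def __post_init__(self) -> None:
        if (self.records["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_orientations(self) -> int:
        return len({p.achieved_orientation_deg for p in self.patterns})

    @property
    def n_periods(self) -> int:
        return len({p.period_mirrors for p in self.patterns})

    def check_identifiable(self) -> None:
        if self.n_orientations < 2 or self.n_periods < 2:
            raise ValueError(
                "calibration needs at least 2 distinct pattern orientations and "
                f"2 distinct periods (got {self.n_orientations} orientations, "
                f"{self.n_periods} periods)"
            )

    # -- text round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False)
        meta = {
            "patterns": [
                {
                    "freq_x": str(p.frequency[0]),
                    "freq_y": str(p.frequency[1]),
                    "phase_index": p.phase_index,
                    "n_phases": p.n_phases,
                    "orientation_index": p.orientation_index,
                    "duty": p.duty,
                }
                for p in self.patterns
            ],
            "illumination": {
                "a_x": self.illumination.direction.x,
                "a_y": self.illumination.direction.y,
                "wavelength_nm": self.illumination.wavelength_nm,
            },
            "main_order": list(self.main_order),
            "state": self.state,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "true_geometry": None
            if self.true_geometry is None
            else {
                "pitch_um": self.true_geometry.pitch_um,
                "width_um": self.true_geometry.mirror_width_um,
                "axis_plus": list(self.true_geometry.axis_plus),
                "axis_minus": list(self.true_geometry.axis_minus),
                "gamma_plus_deg": self.true_geometry.gamma_plus_deg,
                "gamma_minus_deg": self.true_geometry.gamma_minus_deg,
                "label": self.true_geometry.label,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationDataset":
        from fractions import Fraction

        path = Path(path)
        records = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        patterns = [
            PatternSpec(
                frequency=(Fraction(p["freq_x"]), Fraction(p["freq_y"])),
                phase_index=p["phase_index"],
                n_phases=p["n_phases"],
                orientation_index=p["orientation_index"],
                duty=p["duty"],
            )
            for p in meta["patterns"]
        ]
        ill = PlaneWave(
            Direction.incoming(meta["illumination"]["a_x"], meta["illumination"]["a_y"]),
            meta["illumination"]["wavelength_nm"],
        )
        tg = meta["true_geometry"]
        true_geom = (
            None
            if tg is None
            else MirrorGeometry(
                pitch_um=tg["pitch_um"],
                mirror_width_um=tg["width_um"],
                axis_plus=tuple(tg["axis_plus"]),
                axis_minus=tuple(tg["axis_minus"]),
                gamma_plus_deg=tg["gamma_plus_deg"],
                gamma_minus_deg=tg["gamma_minus_deg"],
                label=tg["label"],
            )
        )
        return cls(
            patterns=patterns,
            records=records,
            illumination=ill,
            main_order=DiffractionOrder(*meta["main_order"]),
            state=meta["state"],
            noise_sigma=meta["noise_sigma"],
            seed=meta["seed"],
            true_geometry=true_geom,
        )


def default_calibration_patterns() -> list[PatternSpec]:
    """Standard calibration series: stripe gratings over periods 2–9 mirrors.

    Spans six periods and several orientations so that the axis tilts and
    the rotation angle are all well identified: the short-period gratings
    throw suborders far into the envelope wings (strong leverage on γ),
    the mixed orientations separate the two axis tilts.
    """
    layout = [
        (2, 0.0), (2, 90.0), (3, 0.0), (3, 90.0), (4, 0.0), (4, 90.0),
        (5, 45.0), (5, 135.0), (7, 0.0), (7, 90.0), (9, 30.0), (9, 120.0),
    ]
    return [
        PatternSpec.from_period(p, orientation_deg=phi, orientation_index=i)
        for i, (p, phi) in enumerate(layout)
    ]


def _predicted_intensities(
    geom: MirrorGeometry,
    patterns: Sequence[PatternSpec],
    illumination: PlaneWave,
    main: DiffractionOrder,
    state: MirrorState,
    radius: int,
    coef_cache: dict | None = None,
) -> pd.DataFrame:
    rows = []
    for idx, spec in enumerate(patterns):
        subs = pattern_suborders(
            spec, illumination.direction, illumination.wavelength_nm, geom, state, main, radius
        )
        for s in subs:
            rows.append({"pattern_index": idx, "harmonic": s.harmonic, "intensity": s.intensity})
    return pd.DataFrame(rows)


def simulate_calibration(
    true_geom: MirrorGeometry,
    patterns: Sequence[PatternSpec],
    illumination: PlaneWave,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    main_order: DiffractionOrder | tuple[int, int] = (-6, 0),
    state: MirrorState = "-",
    radius: int = 2,
) -> CalibrationDataset:
    """Forward-simulate a suborder-intensity measurement series.

    Intensities are the diffraction model's predictions perturbed by
    multiplicative Gaussian noise (relative sd ``noise_sigma``, a proxy for
    camera shot/gain noise) and clipped at zero; the run is reproducible
    from ``seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if len({p.achieved_orientation_deg for p in patterns}) < 2:
        raise ValueError("calibration patterns must span at least 2 orientations")
    main = DiffractionOrder(*main_order)
    records = _predicted_intensities(true_geom, patterns, illumination, main, state, radius)
    rng = np.random.default_rng(seed)
    noisy = records["intensity"].to_numpy() * (
        1.0 + noise_sigma * rng.standard_normal(len(records))
    )
    records["intensity"] = np.clip(noisy, 0.0, None)
    return CalibrationDataset(
        patterns=list(patterns),
        records=records,
        illumination=illumination,
        main_order=main,
        state=state,
        noise_sigma=noise_sigma,
        seed=seed,
        true_geometry=true_geom,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("axis_tilt1_deg", "axis_tilt2_deg", "gamma_deg")


def _axis_from_tilts(axis0: np.ndarray, t1_deg: float, t2_deg: float) -> np.ndarray:
    """Rotate the reference axis by two tilts about transverse directions.

    Parameterizing the axis by tilt angles from its reference direction
    avoids the unit-norm constraint in the optimizer.
    """
    u1 = np.cross(axis0, [0.0, 0.0, 1.0])
    if np.linalg.norm(u1) < 1e-6:
        u1 = np.cross(axis0, [1.0, 0.0, 0.0])
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis0, u1)
    m = build_rotation(u1, t1_deg) @ build_rotation(u2, t2_deg) @ axis0
    return m / np.linalg.norm(m)


class _FastForward:
    """Vectorized suborder-intensity model for repeated fit evaluations.

    Pattern Fourier magnitudes and suborder frequency offsets do not depend
    on the mirror parameters, so they are precomputed once; each geometry
    evaluation is then a handful of numpy array operations.  Agrees with
    :func:`dmdsim.diffraction.pattern_suborders` to round-off (tested).
    """

    def __init__(self, dataset: CalibrationDataset, radius: int):
        from .sim_patterns import pattern_fourier_coefficient

        a = dataset.illumination.direction
        lam = dataset.illumination.wavelength_nm
        ld = lam * 1e-3
        self._a = a.as_array()
        self._lam_um = ld
        ks = np.arange(-radius, radius + 1)
        self._pattern_index = np.repeat(np.arange(len(dataset.patterns)), len(ks))
        coefs, nus = [], []
        for spec in dataset.patterns:
            fx, fy = (float(f) for f in spec.frequency)
            for k in ks:
                coefs.append(abs(pattern_fourier_coefficient(spec, int(k))))
                nus.append((k * fx, k * fy))
        self._c2 = np.asarray(coefs) ** 2
        self._nu = np.asarray(nus)  # (N, 2)
        self._main = np.asarray(dataset.main_order, dtype=float)
        self._n_patterns = len(dataset.patterns)

    def intensities(self, geom: MirrorGeometry, state: MirrorState) -> np.ndarray:
        ld = self._lam_um / geom.pitch_um
        b_xy = self._a[:2] + ld * (self._main + self._nu)
        r2 = np.einsum("ij,ij->i", b_xy, b_xy)
        ok = r2 <= 1.0
        bz = np.sqrt(np.clip(1.0 - r2, 0.0, None))
        u = self._a[None, :] - np.column_stack([b_xy, bz])
        R = geom.rotation(state)
        w_over_lam = geom.mirror_width_um / self._lam_um
        env = (
            np.sinc(w_over_lam * (u @ R[:, 0])) * np.sinc(w_over_lam * (u @ R[:, 1]))
        ) ** 2
        return np.where(ok, self._c2 * env, 0.0)

    def normalized(self, geom: MirrorGeometry, state: MirrorState) -> np.ndarray:
        raw = self.intensities(geom, state)
        totals = np.bincount(self._pattern_index, weights=raw, minlength=self._n_patterns)
        return raw / totals[self._pattern_index]


class MirrorCalibrationModel:
    """Least-squares model for mirror rotation axis and angle.

    Parameters
    ----------
    dataset : CalibrationDataset
        Measured (pattern, suborder) → relative intensity records.  Must
        contain at least two distinct orientations and periods.
    init : MirrorGeometry
        Starting geometry; its axis for the fitted state is the reference
        direction of the tilt parameterization.
    radius : int
        Suborder harmonics included in the forward model.

    Pitch and mirror width are held fixed: relative suborder intensities do
    not constrain them.  Intensities are normalized per pattern (model and
    data alike), which makes the fit invariant to a global rescaling of the
    measurements.
    """

    def __init__(self, dataset: CalibrationDataset, init: MirrorGeometry, radius: int = 2):
        dataset.check_identifiable()
        self.dataset = dataset
        self.init = init
        self.radius = radius
        self._axis0 = init.axis(dataset.state)
        self._data_norm = self._normalize(dataset.records)
        self._forward = _FastForward(dataset, radius)

    @staticmethod
    def _normalize(records: pd.DataFrame) -> np.ndarray:
        df = records.sort_values(["pattern_index", "harmonic"]).reset_index(drop=True)
        totals = df.groupby("pattern_index")["intensity"].transform("sum")
        return (df["intensity"] / totals).to_numpy()

    def _geometry_at(self, params: np.ndarray) -> MirrorGeometry:
        t1, t2, gamma = params
        m = tuple(float(c) for c in _axis_from_tilts(self._axis0, t1, t2))
        if self.dataset.state == "-":
            return self.init.replace(axis_minus=m, gamma_minus_deg=float(gamma))
        return self.init.replace(axis_plus=m, gamma_plus_deg=float(gamma))

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        geom = self._geometry_at(params)
        return self._forward.normalized(geom, self.dataset.state) - self._data_norm

    def fit(self, max_nfev: int = 400, scan_half_width_deg: float = 20.0,
            scan_points: int = 11, gamma_scan_deg: float = 2.0,
            n_starts: int = 3) -> "MirrorCalibrationResults":
        """Coarse parameter scan followed by multi-start bounded least squares.

        The residual landscape is multi-modal in the axis tilts (distinct
        tilt directions can blaze different suborders similarly), so the
        local solver is run from the ``n_starts`` best points of a coarse
        (t1, t2, γ) grid and the lowest final cost is kept.
        """
        gamma0 = self.init.gamma_deg(self.dataset.state)
        starts = [np.array([0.0, 0.0, gamma0])]
        if scan_points > 1:
            grid = np.linspace(-scan_half_width_deg, scan_half_width_deg, scan_points)
            gammas = gamma0 + np.arange(-gamma_scan_deg, gamma_scan_deg + 0.5)
            scored = []
            for g in gammas:
                for t1 in grid:
                    for t2 in grid:
                        r = self._residuals(np.array([t1, t2, g]))
                        scored.append((float(r @ r), (t1, t2, g)))
            scored.sort(key=lambda s: s[0])
            starts = [np.array(p) for _, p in scored[:n_starts]]
        # physical box keeps the optimizer on valid mirror kinematics
        sign = math.copysign(1.0, gamma0)
        lo = [-45.0, -45.0, min(sign * 1.0, sign * 89.0)]
        hi = [45.0, 45.0, max(sign * 1.0, sign * 89.0)]
        best_res = None
        for x0 in starts:
            res = least_squares(
                self._residuals, x0, bounds=(lo, hi), max_nfev=max_nfev, xtol=1e-12
            )
            if best_res is None or res.cost < best_res.cost:
                best_res = res
            if best_res.cost < 1e-20:
                break
        results = MirrorCalibrationResults(self, best_res)
        if not best_res.success:
            raise ConvergenceError(
                f"calibration fit did not converge: {best_res.message}", results
            )
        return results


class MirrorCalibrationResults:
    """Estimates, uncertainties and diagnostics of a mirror-parameter fit."""

    def __init__(self, model: MirrorCalibrationModel, opt_result):
        self.model = model
        self._res = opt_result
        self.params = pd.Series(opt_result.x, index=_PARAM_NAMES)
        self.nobs = len(opt_result.fun)
        self.df_resid = max(self.nobs - len(opt_result.x), 1)
        self.ssr = float(opt_result.fun @ opt_result.fun)
        self.scale = self.ssr / self.df_resid
        J = opt_result.jac
        try:
            cov = self.scale * np.linalg.inv(J.T @ J)
            self.bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=_PARAM_NAMES)
        except np.linalg.LinAlgError:
            self.bse = pd.Series(np.full(len(_PARAM_NAMES), np.nan), index=_PARAM_NAMES)

    @property
    def fitted_geometry(self) -> MirrorGeometry:
        geom = self.model._geometry_at(self.params.to_numpy())
        return geom.replace(label=(self.model.init.label or "geometry") + "-fitted")

    @property
    def gamma_deg(self) -> float:
        return float(self.params["gamma_deg"])

    @property
    def axis_change_deg(self) -> float:
        """Angle between the fitted axis and the initialization axis."""
        m = np.asarray(self.fitted_geometry.axis(self.model.dataset.state))
        c = float(np.clip(m @ self.model._axis0, -1.0, 1.0))
        return math.degrees(math.acos(c))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Linearized (Jacobian-based) confidence intervals; approximate."""
        from scipy.stats import t

        q = t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def half_widths(self, alpha: float = 0.05) -> pd.Series:
        ci = self.conf_int(alpha)
        return (ci["upper"] - ci["lower"]) / 2.0

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Mirror rotation calibration (least squares)",
            "=" * 46,
            f"state: {ds.state}   main order: {tuple(ds.main_order)}   "
            f"wavelength: {ds.illumination.wavelength_nm:g} nm",
            f"patterns: {len(ds.patterns)}  ({ds.n_orientations} orientations, "
            f"{ds.n_periods} periods)   observations: {self.nobs}",
            f"residual sum of squares: {self.ssr:.3e}   noise sigma (data): {ds.noise_sigma:g}",
            "-" * 46,
            f"{'parameter':<16}{'estimate':>10}{'std err':>10}",
        ]
        for name in _PARAM_NAMES:
            lines.append(f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}")
        lines.append("-" * 46)
        lines.append(f"axis change from init: {self.axis_change_deg:.3f} deg")
        return "\n".join(lines)


def fit_mirror_params(
    data: CalibrationDataset, init: MirrorGeometry, radius: int = 2
) -> tuple[MirrorGeometry, float, pd.Series]:
    """Functional wrapper: fitted geometry, residual SSR, confidence half-widths."""
    results = MirrorCalibrationModel(data, init, radius=radius).fit()
    return results.fitted_geometry, results.ssr, results.half_widths()


def predicted_contrast_from_fit(
    fitted: MirrorGeometry,
    anchor_order: tuple[int, int] = (-6, 0),
    anchor_wavelength_nm: float = 488.0,
    second_order: tuple[int, int] = (-5, 0),
    second_wavelength_nm: float = 635.0,
    state: MirrorState = "-",
    train: OpticalTrain | None = None,
) -> dict[float, ContrastRecord]:
    """Predicted SIM contrast per color for a two-color design on a geometry.

    Chains the in-plane blaze optimization, the second-color realignment and
    the suborder/imbalance/contrast model.
    """
    anchor = solve_inplane(anchor_order, anchor_wavelength_nm, fitted, state)
    _, records = two_color_compromise(
        anchor, second_wavelength_nm, second_order, fitted, train=train
    )
    return records
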