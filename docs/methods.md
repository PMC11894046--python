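# Methods

## Diffraction model

The mirror array is a square lattice of pitch *d* in the backplane plane
(ê_x, ê_y), normal ê_z.  Directions are unit vectors; incoming beams have
a_z = −√(1−a_x²−a_y²) < 0, outgoing b_z > 0.  The lattice grating equations
couple the transverse components, b_x − a_x = n_x λ/d and
b_y − a_y = n_y λ/d, for integer order indices (n_x, n_y).  An order whose
transverse components exceed unit norm is evanescent and is represented as
a value (`None`), not an error, so design code can constrain against it.

Each landed mirror state is a rotation R(m̂, γ) of the backplane frame
(Rodrigues construction via `scipy.spatial.transform.Rotation`; no Euler
convention is exposed).  The mirror frame is ê_i = R ê_α; ê_3 is the facet
normal.  The blaze condition is specular reflection off the facet:
b₁ = a₁, b₂ = a₂, b₃ = −a₃ in the mirror frame.  Combined with the two
grating equations this is seven equations in six unknowns; exact solutions
exist only when R₁₃/R₂₃ is rational with small numerator/denominator, in
which case the blazed orders satisfy n_x/n_y = R₁₃/R₂₃.  For the
corner-illumination pixel (CIP) the ratio is −1 (orders n_x = −n_y); for
the tilt-and-roll (TRP) − state it is 90.523, so no physical order is
exactly blazed and the (n, 0) orders are near-blazed because only the small
ê_z component of the rotation axis spoils them.  (The two equations that
define the exact-solution ratio associate n_x with R₁₃; the package uses
that association consistently.)

### Blaze envelope

The single-mirror intensity envelope is the scalar Fraunhofer factor of a
tilted square facet of width *w*:

    E(â, b̂) = sinc²[(w/λ)(â−b̂)·ê₁] · sinc²[(w/λ)(â−b̂)·ê₂]

normalized to 1 at its peak, which is attained exactly at the specular
direction.  *w* defaults to 0.92 d (typical fill factor).  Only the
envelope — and therefore only the predicted suborder imbalance — depends on
w; all blaze-geometry outputs (angles, Δ_b) are independent of it.
Polarization, inter-mirror shadowing and window reflections are not
modelled (scalar diffraction).

### Blaze violation and cost

Δ_b is the angle between the diffracted output and the specular reflection
of the same input (output-side definition; an input-side definition would
differ only at third order in Δ).  The optimization cost is the in-facet
transverse mismatch C = (b₁−a₁)² + (b₂−a₂)².  It deliberately omits the
b₃+a₃ term: the resulting problem reduces to one dimension and still
reproduces every exact solution when one exists.

## Solver

On the constraint manifold the mirror-frame mismatches are affine in the
single scalar Δz = b_z − a_z:

    b_i − a_i = K_i + R_{3i}·Δz,   K_i = ν_x R_{1i} + ν_y R_{2i},

with ν = (n_x λ/d, n_y λ/d).  C is therefore a parabola in Δz with
closed-form minimizer Δz*, and the Lagrange stationary set is the level
curve Δz(a_xy) = Δz* — this is why optimal solutions form one-parameter
families (closed curves in (b_x, b_y)).  The solver:

- traces the level curve in polar coordinates about the symmetric point
  a_xy = −ν/2 (the concavity of Δz makes the radial crossing unique;
  `brentq` at 1e-14), attaching an arc-length family parameter in [0, 1);
- detects degenerate single-point families when Δz* exceeds the feasible
  maximum 2√(1−|ν|²/4) (e.g. the 635 nm (0,−6) and (0,−5) orders of the
  TRP preset), collapsing to a_xy = −ν/2;
- reports Lagrange multipliers (α, β) = −∂C/∂(b_x, b_y) as diagnostics;
  the full Lagrangian gradient at returned points is below 1e-6 (tested);
- returns the in-plane solution as the family point with zero out-of-plane
  components, choosing of the two crossings the branch with incoming and
  outgoing beams on the positive-component side (the experimentally
  convenient one).  Angle values are rounded only at presentation; tests
  compare unrounded values at 0.05° against the reference design numbers.

Two-color compromise alignment holds the anchor's output direction fixed
and solves the grating equations for the second color's incidence; the
added blaze violation and the per-color contrast are then evaluated.

## SIM patterns, contrast and optics arithmetic

Gratings are binary threshold patterns on the mirror lattice,
on(i,j) ⇔ frac(f_x i + f_y j + k/n) < duty, with a rational frequency
vector (f_x, f_y) in cycles/mirror.  Rationality makes the pattern exactly
periodic, so discrete Fourier coefficients are computed over one period
cell without leakage; the threshold is evaluated in integer arithmetic so
lattice sites on the duty boundary are classified consistently across
phase steps.  Phase index k shifts the grating by k/n of a period; when n
divides the period denominator this is an exact lattice translation and
the harmonic magnitudes/phase spacing are exact (tested to 1e-9);
otherwise a small phase-stepping error of order the sub-mirror shift
remains, which mirrors the behaviour of real displays.

A displayed grating adds suborders around each lattice order at
b_xy = b_xy(main) + (λ/d)·k·(f_x, f_y) with amplitude |c_k|·√E.  The SIM
fringe is written by the two k = ±1 suborders passed by the Fourier mask
(main order blocked), so the sample fringe period is **half** the imaged
grating period; the shipped two-color design uses 310 nm (488 nm) and
425 nm (635 nm) fringes, i.e. 6.89- and 9.44-mirror gratings on the 60×
train, giving a frequency-support factor (2NA/λ + 1/p)/(2NA/λ) ≈ 1.55.
Beam imbalance η = min(I₊,I₋)/max(I₊,I₋) degrades the fringe contrast to
m = 2η/(1+η²).  Contrast predictions default to the in-plane pattern
orientation; η depends noticeably on orientation (the envelope is sampled
along the fringe direction), which is why a multi-orientation set brackets
the per-color contrast rather than pinning a single value.

Optical-train arithmetic is pure imaging algebra: sample period =
DMD period × pitch × (f₂/f₁)/mag; effective camera pixel =
pitch/(mag·post-mag); Nyquist distance λ/(4NA).  Fourier-mask hole
positions are r = f₁·tan(angle to the main-order axis), decomposed in the
mask plane; default hole radius 0.5 mm (configurable — the physical mask
is a pierced foil with no canonical dimension).  Acquisition frames are
ordered lexicographically (z, wavelength, orientation, phase); defaults
are 3 orientations × 3 phases per color, the standard 2D-SIM choice.

## Shipped presets

- `TRP-DLP4710-nominal` — d = 5.4 μm; − state axis (0, −cos δ, sin δ),
  + state the same under 90° rotation about ê_z; γ = 16.9548°,
  δ = 4.2505°.  The two free parameters are pinned by the characterized
  rotation-matrix ratio R₁₃⁻/R₂₃⁻ = 90.523 together with a least-squares
  match to the device's known blazed two-color solutions at 488/635 nm;
  the preset then reproduces all of those solutions to better than 0.05°.
- `TRP-DLP4710-fitted` — γ = 17.7° with the axis azimuth rotated 13° in
  the backplane, the characterized deviation of a real device from nominal
  kinematics; it raises typical blaze violations to the ~3° level.  The
  direction of the azimuth change is a convention choice (only its
  magnitude is characterized).
- `CIP-nominal` — d = 7.56 μm, diagonal axis (1,1,0)/√2, γ± = ±12°.

Presets serialize to TOML (pitch_um, width_um, axis_plus/minus,
gamma_plus/minus_deg) and calibration writes fitted presets in the same
format.

## Calibration

The forward simulator predicts relative suborder intensities for a series
of displayed gratings under fixed illumination and perturbs them with
multiplicative Gaussian noise (relative sd σ, a camera shot/gain proxy),
clipped at zero and reproducible from a seed.  The fit estimates the
rotation axis (two tilt angles about the initialization axis, avoiding the
unit-norm constraint) and γ by least squares on per-pattern-normalized
intensities, making it invariant to global intensity rescaling.  Pitch and
mirror width are held fixed — relative intensities do not identify them.
The default calibration series spans periods 2–9 mirrors over several
orientations: short periods throw suborders into the envelope wings
(leverage on γ), mixed orientations separate the two tilts.  At least two
distinct orientations and two distinct periods are required or the model
refuses to fit.

The residual landscape is multi-modal in the axis tilts, so the solver
runs bounded least squares from the best few points of a coarse
(t₁, t₂, γ) grid and keeps the lowest cost.  Confidence half-widths come
from the Jacobian at the optimum (linearized, approximate).  With the
default series, noiseless data recover the axis to < 0.05° and γ to
< 0.01°; at 2% noise the mean γ error over 50 seeds is < 0.1° (tested).

## What the synthetic data do and do not show

The simulator draws from the same scalar-diffraction model the fit
inverts, so recovery tests demonstrate identifiability, optimizer
correctness and noise robustness — not model adequacy on a real device,
where polarization, window aberrations, mirror flatness and detector
nonlinearity all enter.  Predicted contrast values inherit the same
caveat: they are upper bounds of the scalar model for the chosen pattern
orientation.

## Numerical choices

Constraint residuals are satisfied to ~1e-12 (closed-form substitution);
stationarity to 1e-8 or better; family closure/degeneracy detected at
1e-4 curve extent; rotation matrices validated at 1e-10.  Rational
approximations of pattern frequencies use denominators ≤ 256 by default
(achieved vs target period both reported).  Exported JSON uses sorted keys
and 6-significant-digit floats for byte-identical reruns.

## Known limitations

No vector/polarization diffraction ("pizza-polarizer" contrast gains are
out of scope), no mirror-flatness or protective-window modelling, no
wavelength optimization, no 3D-SIM (three-beam) mask mode, no instrument
control.  The fitted preset's azimuth-direction convention and the
contrast orientation dependence are documented above; reference per-color
imbalance figures for a specific device depend on its exact fitted axis
and pattern set and are reproduced here in magnitude, not asserted
digit-for-digit.
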