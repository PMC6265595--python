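# Methods

## Model

The arm is two rigid segments in a horizontal plane: proximal (shoulder)
length `L_s`, distal (elbow) length `L_e`, shoulder axis at the origin.
Joint angles are counter-clockwise in radians: `alpha_s` from the X-axis,
`alpha_e` from the prolongation of the proximal segment, with
`alpha_s in [0, pi)` and `alpha_e in [0, pi]` (a right-arm layout; the
mirrored left-arm sign convention is not implemented). The hand, with the
wrist immobilised, is the end-point

```
x = L_s cos(alpha_s) + L_e cos(alpha_s + alpha_e)
y = L_s sin(alpha_s) + L_e sin(alpha_s + alpha_e)
```

An isometric force of amplitude `F` and direction `theta` is generated at
the end-point. Equating the work of the joint torques under virtual joint
rotations to the work of the force along the induced end-point
displacement gives pure sinusoids in theta:

```
M_s = F h_s sin(theta - gamma_s)       M_e = F L_e sin(theta - gamma_e)
```

with `h_s = |(x, y)|` the shoulder-to-hand distance and the
*characteristic angles* `gamma_s = atan2(y, x)` (direction of the
shoulder-to-hand line, suitably unwrapped — see below) and
`gamma_e = alpha_s + alpha_e` (direction of the elbow-to-hand line).
Positive torque is counter-clockwise, which in this layout means flexor
loading. The model is purely static: no inertial or interaction torques,
no antagonist co-activation, no biarticular muscles, no
activation-to-force dynamics. It applies to isometric contractions or
quasi-static force tracing only.

### Assumptions

- Equal segment lengths (`L_s = L_e = 0.5` in working-space-radius units)
  are the default, matching typical human proportions within a few
  percent; all closed-form shortcut identities (`gamma_s = alpha_s +
  alpha_e/2`, `h_s = 2L cos(alpha_e/2)`, lag `= alpha_e/2`) assume them.
  The general unequal-length case is supported through the coordinate
  route for kinematics, torques and sector analysis; the isosceles
  shortcuts then serve only as test oracles.
- `alpha_e = pi` (complete elbow flexion) puts the end-point on the
  shoulder axis, where `gamma_s` is undefined. This configuration is
  idealised; the library raises `DegenerateConfiguration` rather than
  assigning a conventional angle (threshold `h_s <= 1e-9 R`). Limits as
  `alpha_e -> pi` (e.g. the sector weights converging to 0.5/0.5) are
  obtained analytically from the phase lag, which stays well-defined.

## Numerical choices

**Branch unwrapping of gamma_s.** The principal two-argument arctangent
wraps at pi, but `gamma_s` ranges up to `27 pi / 20` on the canonical
grid. The implementation shifts the principal value by the multiple of
`2 pi` nearest to the anchor `alpha_s + alpha_e / 2`; the anchor is the
exact value for equal segments and within `pi/2` of the true angle for
any lengths (since the shoulder-to-hand direction always lies between
`alpha_s` and `alpha_s + alpha_e`), so the unwrap is unambiguous. This
keeps `gamma_s` continuous and affine in both joint angles, which the
family analysis relies on.

**Coordinate cross-check route.** An independent reconstruction of the
characteristic angles from `(x, y)` alone — phase lag from
`arccos(h_s / 2L)`, `gamma_s` from `arccos(x / h_s)` — is retained for
verification. Being arccos-based it is quadrant-blind, so it is
restricted to equal lengths and the upper half-plane (`y >= 0`), which
covers the canonical grid; outside that domain it raises rather than
guessing. Both routes agree to < 1e-9 wherever both apply.

**Torque-wave sampling.** Waves are sampled at 1000 uniform directions on
the half-open `[0, 2 pi)` by default. Peak amplitudes read off a sampled
wave are exact when the sine maximum falls on a grid node (as it does for
the canonical configurations, where the phases are multiples of the
sample spacing) and otherwise within `(pi/n)^2 / 2` of the analytic
amplitude.

**Statics oracles.** Two independent checks validate the sinusoid
torques. The virtual-work oracle perturbs both joint angles by a common
`delta`, displaces the end-point by *exact* forward kinematics (not the
small-arc approximation, which is itself the first-order statement being
validated), and measures the work mismatch; the residual is the
second-order Taylor remainder and shrinks ~4x when delta is halved. The
Jacobian-transpose oracle computes `tau = J^T F` from the analytic
kinematic Jacobian and agrees with the closed form to < 1e-10 on random
configurations of any segment lengths.

**Sector decomposition.** Sectors are half-open `[start, end)` intervals
between consecutive sorted force singular points, so membership is a
partition; a force direction within 1e-12 of a singular point raises
`OnBoundary` instead of being assigned arbitrarily. The degenerate
extended-elbow case (`gamma_s = gamma_e`, the two torques changing sign
together) is reported as two coinciding-direction sectors with
`w_TOD = 0` rather than four sectors two of which have zero width.
Weights come from the closed form; the sampling integral over 1e4
directions is used only as a test cross-check.

**Family analysis.** Slopes are recovered by least squares per trace and
averaged, rather than read from the closed form, so the check exercises
the grid-construction pipeline end to end; because the model is exactly
affine in the joint angles the fits agree across lines to roundoff and
are asserted at 1e-12. Spacing is the mean offset between adjacent
fixed-value lines at matched varying-angle indices; it is NaN (reported
as not applicable) for single-line families. The isotropy flag holds when
the torque-phase lag varies by < 1e-9 along every trace. Grid angles are
computed as `index * step` by multiplication, never by running summation,
so grids are bit-identical across runs.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `l_s`, `l_e` | working-space radii | 0.5, 0.5 | segment lengths; defaults normalise the reach to R = 1 |
| `alpha_step` | rad | pi/10 | joint-angle grid step |
| `alpha_max_index` | — | 9 | highest grid index (10 values per angle, 0 .. 9 pi/10) |
| `theta_samples` | — | 1000 | force directions per cycle |
| `force` | arbitrary | 1.0 | force amplitude; torques are in force x length units |
| `seed` | — | 0 | RNG seed for the random-configuration oracle sweeps only |

The canonical 10x10 grid with pi/10 steps and 1000-sample cycles is small
enough that every analysis completes in well under a second; the defaults
are the study conditions, not a performance compromise.

## Scope of the deterministic "fixtures"

The package needs no measured data: all inputs are parameter
specifications, and the canonical grid generator (`fixture_grid`) is
deterministic. Consequently the tests demonstrate internal mathematical
consistency of the statics model — they say nothing about how well a real
arm's EMG follows the predicted torque sectors, which depends on
co-activation, hysteresis and biarticular muscles that the model
deliberately excludes.

## Known limitations

- Statics only; velocities, accelerations and interaction torques are out
  of scope, as are muscle-level quantities (EMG amplitudes, named
  muscles, antagonist co-activation).
- The torque-sign-to-flexor mapping is fixed to the right-arm planar
  layout; mirrored configurations would need a sign flip that is not
  implemented.
- Inverse kinematics (end-point to joint angles) is not provided; all
  traces are generated in joint space.
- The coordinate cross-check route does not extend below the X-axis or to
  unequal segments by construction.
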