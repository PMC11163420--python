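# Methods

## Physical model

All nuclei are spin-1/2 (¹³C, ¹⁵N). The simulated Hamiltonian contains
only the terms that drive the recoupling experiments analyzed here:

* heteronuclear secular dipolar coupling, `ω(t)·2IᵢzSₖz`;
* homonuclear secular dipolar coupling with flip-flop,
  `ω(t)·(2IᵢzIⱼz − ½(Iᵢ₊Iⱼ₋ + Iᵢ₋Iⱼ₊))`;
* chemical-shift anisotropy as an `ω_CSA(t)·Iz` term, included only for
  sites that carry a tensor (the ¹³C–¹³C constant-time simulations of
  backbone carbonyls, δ_aniso = −75 ppm, η = 0.75, converted to rad/s at
  the ¹³C Larmor frequency of an 11.74 T instrument).

Isotropic shifts, ¹H couplings, rf inhomogeneity and relaxation are
outside the model: the analyzed sites are on-resonance labeled peaks and
the experiments are normalized ratios designed to cancel those effects.
¹⁵N–¹⁵N homonuclear couplings are likewise excluded (nearest ¹⁵N–¹⁵N
distances in the modeled arrays are ≥ 8 Å and the ¹⁵N gyromagnetic ratio
is small). A consequence used by the engine: every ¹⁵N z-projection then
commutes with the full Hamiltonian, so ¹⁵N spins are exact spectators and
REDOR is propagated on the ¹³C subsystem once per classical ¹⁵N spin
configuration (2^nN branches). This is an exact reformulation, not an
approximation.

Magic-angle spinning enters through the orientation of each interaction
tensor in the rotor frame: the coupling coefficient is
`ω(t) = 2π·d · P₂(cos θ(t))` with θ(t) the angle between the (rotating)
internuclear vector and the static field, and the CSA coefficient is the
zz lab component of the rotated shielding tensor. Crystallite orientations
are z-y-z Euler rotations molecule→rotor; the inner angle matters only
for non-axial tensors (the η = 0.75 CSA), and schemes expose
`with_inner_angles(n)` for that case.

### Powder averaging

Default scheme: 377 points, equal weights, deterministic and seed-free —
a golden-ratio (Fibonacci) spiral for the outer two Euler angles plus an
independent √2-based low-discrepancy sequence for the inner angle, i.e. a
quasi-uniform sampling of SO(3) rather than of a single axis direction.
The inner angle matters: a two-angle spiral is quasi-uniform only for the
molecular z axis, and the image of any other fixed direction (such as a
spin array along x) is visibly anisotropic — the full-SO(3) scheme makes
simulated curves invariant under global rotation of the spin system to
< 0.01 at 377 points (tested). A Gauss-Legendre × uniform grid is also
available. Convergence is asserted by a doubling test (two-spin REDOR
changes < 0.01 sup-norm from 256 to 512 orientations). Signals S and S₀ are powder-averaged separately and then
ratioed, matching how the experimental quantities are formed.

## Pulse sequences

**REDOR** (10 kHz MAS default): observe ¹³C, ideal δ-function π pulses on
¹⁵N at each half and full rotor period, one refocusing ¹³C π pulse at the
sequence midpoint replacing the ¹⁵N pulse there; recoupling times are
even multiples of the rotor period (a requested 61.44 ms grid snaps to
61.4 ms at 10 kHz). ΔS/S₀ = 1 − S/S₀ with S₀ from the same propagation
with the ¹⁵N pulses disabled — so S₀ carries the (weak) homonuclear
¹³C–¹³C evolution exactly as the experiment's reference does. Ideal
pulses are justified by the 10 μs experimental π pulses being ≪ the
100 μs rotor period.

**fsREDOR**: the frequency-selective experiment isolates one ¹³C–¹⁵N pair
and removes homonuclear couplings; the implementation is literal about
that model — REDOR on the reduced two-spin system of the selected pair.
Soft-pulse imperfections are not simulated.

**Constant-time ¹³C–¹³C recoupling (PITHIRDS type)** (12.5 kHz MAS): the
total sequence lasts 256 blocks of 3 rotor periods (61.44 ms) regardless
of the effective recoupling time, controlled by block counts (k1, k2, k3).
Recoupling units are finite-pulse trains — one π pulse of one-third rotor
period per rotor period at fixed rotor phase, which recouples the
homonuclear dipolar coupling through the evolution during the pulses —
phased on the XY-8 supercycle in units of 24 pulses (three full XY-8
cycles, net rotation identity) for robustness against the large carbonyl
CSA (the instantaneous CSA offset reaches ~0.5·ω₁ at 11.74 T).
Compensation units in this implementation are rotor-synchronized
free-evolution delays of the same duration: under MAS the secular
dipolar and CSA terms average to zero over each rotor period to first
order, so these units are near-identity propagators. The laboratory
sequence instead keeps pulsing throughout and varies pulse *positions*,
which also equalizes rf heating and relaxation pathways — effects outside
the simulated Hamiltonian. Two documented consequences of this choice:
(i) for a coupling-free site *without* CSA the curve is exactly flat at 1
(the constant-time check); (ii) for a coupling-free site *with* the
carbonyl CSA, imperfect finite pulses in the recoupling train dissipate
roughly 30% of the powder signal over the full 61 ms (measured with this
package's own simulator), a loss common to all curves compared at equal
k1 and therefore largely neutral for distance *ordering*, but a reason
not to read absolute S/S₀ values as pure dipolar dephasing. Several
pulsed compensation patterns (pulse positions advancing by thirds each
period, by quarters each sub-unit, half-and-half) were evaluated with the
same simulator and all recoupled the CSA itself badly enough to corrupt
S₀; the free-evolution compensation was adopted as the faithful-physics
option at this field strength.

Effective recoupling times advance in supercycle units of 24 rotor
periods (1.92 ms at 12.5 kHz).

### Numerical scheme

Piecewise-constant Hamiltonians with matrix exponentials via
eigendecomposition, batched over crystallites (and ¹⁵N branches for
REDOR). Sub-intervals are ≤ 1 μs; within each step the MAS-modulated
coefficients are *averaged* over 8 finer samples, so the step integrates
the rotor modulation to high accuracy while commutator (Magnus) error
remains the only step-size effect. Free evolution exploits conservation
of total Iz (block-diagonal exponentials over Iz sectors) and is stepped
at 12 steps per rotor period in bounded slices. Rotor-period (REDOR) and
supercycle-unit (PITHIRDS) propagators are reused across the time grid by
exponentiation by squaring; cached powers are bit-identical to sequential
multiplication (tested). Validation: the two-spin REDOR engine matches
the analytic universal curve to < 5·10⁻³ sup-norm at 377 orientations
(powder sampling dominates this figure; the propagation itself agrees
with fine-step integration to ~4·10⁻⁴);
multi-¹⁵N REDOR with no homonuclear couplings matches the
product-of-cosines closed form to < 10⁻³; the constant-time sequence at
the default step matches a 50 ns brute-force propagation to < 10⁻³.

## Geometry

Idealized lattices: strand axis x, hydrogen-bond axis y, stacking axis z;
one point per residue (3.5 Å rise), pseudo-atoms at fixed offsets
(N at −1.2 Å, CO at +1.2 Å along the strand). Strand spacing 5 Å, sheet
spacing 10 Å. Antiparallel neighbors are two-fold rotations about z of
the local strand coordinates (antiparallel stacking: about y, flipping
the displayed face); with the Q11 sequence this automatically aligns
F4↔F8 and K3↔E9 across antiparallel interfaces (residue indices summing
to 12). The antiparallel registry offset is not fixed by idealized
geometry and is exposed as `registry_shift` (default 0, i.e. the
symmetric alignment). Side chains are not atomistic: the K3 Nζ / E9 Cδ
salt-bridge sites are pseudo-atoms whose default preset reproduces the
4 Å contact distance across antiparallel neighbor strands. DARR contact
prediction reports residue pairs with any labeled-atom distance ≤ 6 Å
(the empirical crosspeak detectability range), annotated intra-strand /
inter-strand / inter-sheet.

## Estimators

**Mixture fit**: `min ‖y − Σᵢ pᵢ bᵢ‖²` subject to `pᵢ ∈ [0,1]`,
`Σ pᵢ ≤ 1`, in the ΔS/S₀ convention where the non-dephasing (uncoupled,
or parallel-arrangement) remainder is the zero line. Solved exactly by
active-set enumeration of the convex QP (K ≤ 6), so the single-basis case
equals the clipped projection `clamp(⟨y,b⟩/⟨b,b⟩, 0, 1)` to machine
precision. The default fits one free fraction with the remainder implicit
(the arrangement analysis fits the antiparallel fraction, parallel =
remainder); a sum-to-one mode is available and flagged in the output.
95% intervals: residual bootstrap, 1000 resamples, fixed seed 20240524,
with the standard small-sample inflation of the fitted residuals by
√(n/(n−K)) before resampling (fitted residuals underestimate the noise
scale; on 16-point grids the uncorrected intervals measurably
undercover). The CI method for the original peak-fit intervals is not
specified anywhere reproducible, so a distribution-free choice is made
and named.
Parameter recovery is verified at the experimentally relevant fractions
(9%, 22%, 78%): bias < 0.01 over 200 replicates at σ = 0.02 on 16-point
grids, bootstrap coverage ≥ 0.90.

**Peak fit**: sums of Gaussians by least squares (maximum likelihood
under i.i.d. noise), deterministic initialization (centers at the tallest
in-window local maxima, ties toward lower axis values; σ₀ = window/4),
t-based 95% amplitude intervals from the fit covariance.

**Natural-abundance correction**: background spins that do not dephase
contribute a constant fraction f_na of S/S₀;
`E_true = (E_obs − f_na)/(1 − f_na)` inverts the forward model exactly.
A site-counting helper computes f_na; for one labeled carbonyl among ten
chemically overlapping natural-abundance (1.1%) backbone carbonyls,
f_na ≈ 0.099. Which unlabeled carbonyls overlap the analyzed peak is a
parameter — chemical-shift prediction is out of scope.

**β-index**: baseline (polynomial through anchor-window medians; default
anchors 1580–1600 and 1710–1730 cm⁻¹) → Savitzky–Golay smoothing
(9 points, order 3) → three Gaussians starting at 1625/1650/1695 cm⁻¹
with centers bounded to ±8 cm⁻¹ → index = fitted *height* of the
1693–1697 band over the 1624–1632 band (the index literature uses peak
intensities; an area mode exists). Classification: parallel iff
index < 0.1. The smoothing and baseline settings of the original
Mathematica analysis are unstated; the defaults here are conventional
amide-I practice and configurable, and the reference value 0.082 is used
only as a synthetic-construction setpoint, not as a reproduction claim —
the underlying instrument spectrum is not public.

## Synthetic data

Generators are pure functions of (parameters, seed): noisy dephasing
curves are convex mixtures of simulated basis curves plus i.i.d. Gaussian
noise (σ = 0.02 default, the scale of the reported experimental error
bars) on a 16-point 0–61.44 ms grid; amide-I spectra are Gaussian bands
on a polynomial baseline sampled at 1 cm⁻¹. They emulate the *structure*
of the instrument data (mixture composition, band positions, noise
level) but not spectrometer artifacts, heteroscedastic noise, lineshape
asymmetry or baseline nonlinearity beyond polynomials — so passing
recovery tests demonstrates estimator correctness under the stated noise
model, not robustness to every instrumental pathology.

## Problem sizes and defaults

Simulations in the tests and the acceptance script use the canonical
eight-spin arrays with 377 powder orientations for REDOR (seconds to
~1.5 min per curve) and 8 directions × 3 inner angles for the eight-spin
constant-time ¹³C–¹³C curves (~2.5 min per curve), sizes at which the
doubling tests show the reported quantities are converged to well within
their stated tolerances.

## Known limitations

* The constant-time compensation differs from the laboratory sequence as
  discussed above; absolute S/S₀ of CSA-bearing multi-spin systems mixes
  ~tens of percent of pulse-train loss into the decay.
* Ideal-pulse REDOR ignores finite-pulse scaling (sub-percent at the
  10 μs / 100 μs ratio).
* The idealized lattices carry no side-chain atoms, no twist, and no
  disorder; registry alignment in antiparallel models is a parameter, not
  a prediction.
* fsREDOR assumes perfect pair selection.
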