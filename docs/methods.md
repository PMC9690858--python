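# Methods

`isodamage` computes, for light-ion isotopes (¹H–³H, ³He/⁴He, ⁶Li–¹⁴C), the
energy they deposit to a spherical cell-nucleus model and the DNA damage they
induce per unit dose, using deterministic transport plus analytical fitted
yield curves.  This note records the models, the numerical choices, and the
places where the design was genuinely open.

## Transport model

**Stopping powers.**  All transport rests on one reference table: protons in
liquid water on a per-nucleon energy grid (0.001–512 MeV/u, keV/µm).  Two
physical reductions extend it to every supported ion:

* *Isotope invariance.*  Electromagnetic stopping depends on charge and
  velocity only, so isotopes of one element share the proton-scaled stopping
  power at equal energy per nucleon (`ion_stopping` is exactly independent of
  the mass number A).
* *Effective-charge scaling.*  Heavier elements scale from hydrogen at the
  same velocity via `S_ion = S_p · (Z_eff(Z)/Z_eff(1))²` with the Barkas-type
  fraction `Z_eff = Z·(1 − exp(−c·β·Z^(−2/3)))`, β from relativistic
  kinematics (`β² = 1 − (1+E/931.494 MeV)⁻²`) and `c = 125` (the constant is
  exposed and overridable).  At 0.25 MeV/u this gives Z_eff ≈ 3.50 for carbon
  and 0.94 for hydrogen.

**The packaged table is a synthetic reconstruction.**  The shipped CSV
(`data/proton_water_stopping_synthetic.csv`) is *not* a copy of a published
data file.  It is generated from the package's own piecewise model — a
velocity power law `A₂T^0.45` merged harmonically with an empirical
logarithmic branch below 0.5 MeV, a √T law below 10 keV, and a relativistic
Bethe term (I = 75 eV) above 0.5 MeV — whose coefficients were calibrated to
published proton–water anchor values known to about 5 % (26 keV/µm at 1 MeV,
4.6 at 10 MeV, 0.73 at 100 MeV, a Bragg-peak maximum near 82 keV/µm at
0.08 MeV, CSDA ranges of ≈1.7 µm at 0.1 MeV and ≈24.6 µm at 1 MeV).  The
`analytic` table source evaluates the same closed form directly; packaged and
analytic agree to <3 % over 0.01–512 MeV/u.  Users with access to a reference
stopping-power file can load it with `read_table` and pass it everywhere a
table is accepted.

**CSDA ranges and residual energies.**  Ranges use the continuous
slowing-down approximation: straight lines, mean energy-loss rate, no
straggling, no nuclear reactions.  The per-nucleon pathlength integral
`I(E) = ∫ dE'/S_ion(E')` is accumulated by composite trapezoid on a log grid
(2000 points per decade), so `R = A·I(E)` is exactly proportional to A at
fixed element; the trapezoid is exact for constant stopping, which the test
suite exploits as a closed-form oracle.  Residual energy after a pathlength
inverts the same cached integral by interpolation.  Energy below the table
floor (0.001 MeV/u by default) contributes no pathlength and is counted as
deposited locally at the stopping point, conserving energy over a chord.

## Nucleus dosimetry

The source is a circular disk (diameter 10.92 µm) whose plane touches the
spherical nucleus (diameter 10.00 µm) at one pole; particles start
perpendicular to the disk.  A ray at impact parameter b first crosses a water
gap `g(b) = R_n − √(R_n²−b²)`, then the chord `L(b) = 2√(R_n²−b²)`.  Its
deposit is `A·(ε(g) − ε(g+L))` with ε the residual energy per nucleon;
particles stopping before entry deposit nothing, particles stopping inside
deposit everything they carried at entry.

The disk average uses a midpoint rule uniform in b² (uniform areal measure),
starting at 512 points and doubling until the mean changes by <10⁻⁴ relative
(the tolerance is exposed; the closed-form tests tighten it).  Fluence is
normalized to the full source disk, including rays that miss or stop short —
the source defines the fluence reference, and the published ratios are
insensitive to this convention.  Dose per track divides the mean deposit by
the whole nucleus mass (`ρ·π/6·d³`, 1 MeV = 1.602176634×10⁻¹³ J) *even for
stoppers*; the nucleus-averaged LET is the dose-to-fluence ratio, equivalently
`mean deposit × source area / nucleus volume`.

There is no secondary-electron transport: the region-of-interest diameter
(14.22 µm) is recorded but not simulated.  Consequently the high-energy
nucleus-averaged LET reproduces the stopping-power-integrated value (the
ratio is within 1 % at 512 MeV/u) rather than the few-percent-lower values a
full Monte Carlo shows above ~30 MeV/u, where energetic δ-electrons carry
energy out of the nucleus.

Two kinematic regimes are worth naming because tests rely on them.  Below
about 0.3 MeV/u all hydrogen isotopes stop inside the nucleus and the deposit
grows monotonically with A (the heavier isotope simply carries more energy).
Around 0.4–0.8 MeV/u the *lighter* isotope's Bragg peak sits inside the
nucleus while the heavier one punches through, so the ordering inverts before
all isotopes converge at high energy; the isotope spread falls below 3 % by
about 2 MeV/u in this model (at exactly 1 MeV/u it is ≈9 %, a genuine CSDA
feature of the 10 µm geometry).

## Damage-yield curves

Yields are per Gy of nucleus dose and per Gbp of genome, for four classes:
SSB, DSB sites (isolated DSB or clusters counted once), DSB clusters (≥2 DSB
within 25 bp) and total DSB.  Each fitted curve has nine parameters p0–p8;
hydrogen and helium have per-isotope rows, Li–C one row per element (24 rows
total, SHA-256-frozen in the tests).  The registry is extensible through
JSON, which is how the separately published element-level rows for the
non-SSB classes of Li–C can be added.

**Transcription of the curve formula.**  The printed nine-parameter
expression is typographically ambiguous in the source available to this
package.  We enumerated several hundred candidate algebraic compositions
consistent with the printed token order and scored them against every
numerical statement the text makes about the curves (high-energy levels,
low-energy isotope excesses, peak heights and positions, positivity and
isotope convergence).  No composition reproduces all statements
simultaneously.  The implemented reading,

    Y(E) = p0 + p1·E^p2 / (1 + exp(p3)·E^(p2 + q(E))),
    q(E) = sign(p4)·|p4|^p7 / (1 + exp(p5)·E^p6)^p8,

was chosen because (a) it is finite, real and positive for all 24 rows on
their validity domains (several competing readings have poles or complex
values), (b) it reproduces the high-energy anchors best — SSB 146–154 vs
p0 = 156, DSB sites 6.9 vs 6.8, clusters 0.070 vs 0.07 at 512 MeV/u — and
(c) it gives the correct qualitative shapes (monotone SSB, bell-shaped DSB
classes, heavier-isotope excess at low energy).  Known consequences, left
visible rather than patched: the low-energy isotope excesses come out smaller
than the published 30–56 % figures (≈29 % for ³H vs ¹H DSB sites, single-digit
percentages for the others), the hydrogen DSB-site maxima reach ≈9–14 rather
than 16.5–16.9 per Gy per Gbp, and the total-DSB ¹H row misbehaves at high
energy (its p1·e^(−p3) ≈ 88 is not cancelled under *any* candidate reading we
found, which also breaks the mean-cluster-multiplicity ≈ 2.1 check).  The
signed power `sign(p4)·|p4|^p7` is an explicit choice for the one row with
negative p4 and non-integer p7; a literal complex power cannot be what the
original least-squares fit evaluated.

Validity windows are 0.1–512 MeV/u for H/He rows and 0.25–512 MeV/u
otherwise; out-of-window evaluation raises unless an explicit clamp flag is
set (useful when coupling to transport codes that track ions to stopping).

**Derived metrics.**  Isolated DSB = sites − clusters.  Mean cluster
multiplicity = (total − sites + clusters)/clusters (≥2 for sane inputs; a
value in [1,2) triggers a warning).  Per-track yields multiply the per-dose
yield by the dose per track and the genome length; the default genome is
6.6 Gbp (diploid human) — the published per-track claims are all ratios in
which this factor cancels, so the default matters only for absolute counts.
Poisson-scored relative standard deviations are 1/√N.

**Energy grids.**  The simulation grid is log-equidistant with factor-2 steps
from 0.25 to 512 MeV/u (12 values); H and He prepend a low-energy extension
{0.1, 0.125, 0.15, 0.175, 0.2, 0.3, 0.35, 0.4, 0.5, 0.7}, chosen as a
reasonable densification of the region of maximal isotope specificity (the
source states only that extra low-energy values were used).

## Refitting

`fit_eq1` / `YieldCurveFitter` refit the curve family to (E, Y, σ) data with
p0 held fixed (freeing it is rejected by contract — it is set externally as
the high-energy level).  Residuals are weighted 1/σ² in linear yield space by
default, with a log-space option; the free parameters are p1–p6, plus p7–p8
for the total-DSB class.  Optimization is Levenberg–Marquardt with 32
multi-start perturbations, log-uniform within a factor 3 of the
initialization (the registry row of the same class/species when available),
deterministic under the seed.  Because the family is over-parameterized, the
acceptance notion is *curve* recovery: with 1 % multiplicative Gaussian noise
on the standard grid, the refitted curve stays within 2 % RMS of the
generating curve.  `simulate_yield_data` emulates only the statistical
scatter of Monte Carlo damage scoring — multiplicative Gaussian noise with
known σ — not systematic effects (energy-correlated bias, non-Gaussian tails,
detection thresholds), so passing recovery tests demonstrates estimator
correctness, not robustness to real-data systematics.

## Problem sizes and determinism

Everything is deterministic given the configuration and seed.  Default sizes:
2000 quadrature points per decade for range integrals, 512-point starting
disk quadrature with doubling to 10⁻⁴ relative, 1000-point log grids for
curve maxima, 10⁶ samples for the Monte Carlo disk-average cross-check in the
tests, 1 nm steps for the brute-force Euler transport oracle.  These sizes
make every computation in the package a matter of seconds on one core while
keeping quadrature error far below the tolerances of the physical checks.

## Known limitations

* No secondary-electron transport, no straggling, no nuclear reactions, no
  lateral scattering: deposits are upper-bound-faithful CSDA values.
* The packaged stopping table is a calibrated reconstruction (≈5 % at the
  anchor points), not a published dataset; isotope *ratios* are much less
  sensitive to it than absolute deposits.
* The yield-formula transcription is uncertain as described above; per-dose
  yield *levels* at high energy are reliable, low-energy isotope *contrasts*
  are understated, and the total-DSB ¹H row should not be trusted above a few
  MeV/u.
* Charge-state-resolved transport (H⁺/H⁰, He charge states) is out of scope;
  its macroscopic effect is folded into the stopping table.
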