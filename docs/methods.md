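# Methods

## Physical model

The pipeline analyses fluorescence quenching of serum albumin's intrinsic
Trp/Tyr emission by a titrated ligand. Two descriptions are used, matching
the two classical transforms:

**Stern-Volmer law.** F₀/F = 1 + K_q·τ₀·[Q] = 1 + K_SV·[Q], where F₀ and F
are intensities without and with quencher, [Q] the quencher concentration
and τ₀ the unquenched excited-state lifetime (default 6.3×10⁻⁹ s, the
accepted HSA value). The fit is ordinary least squares of F₀/F on [Q] over
the positive-[Q] points with a *free* intercept — the intercept's deviation
from 1 is itself diagnostic, so pinning it would destroy information. A
pin-intercept option exists for the one-parameter form. K_q = K_SV/τ₀ is an
exact arithmetic identity on every fit; K_q far above the diffusion-limited
dynamic ceiling (10¹⁰ L·mol⁻¹·s⁻¹) indicates ground-state complex formation
(static quenching).

**Mechanism call.** `static` requires K_q > threshold and an intercept
consistent with 1, where "consistent" means within a 5% relative tolerance
*or* 1 lying inside intercept ± 2·SE. The two-SE branch matters: a fit with
intercept 0.91 ± 0.06 is consistent with 1 (interval 0.79–1.03) while
1.10 ± 0.01 is not (1.08–1.12) and is flagged `mixed_flagged` — possible
combined static+dynamic quenching. K_q at or below the ceiling gives
`dynamic_consistent`.

**Double-log isotherm.** log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q], fit by
OLS; the intercept is the base-10 log of the association constant and the
slope the apparent binding-site number. ΔG = −RT·ln K_b with
R = 8.314 J·mol⁻¹·K⁻¹, reported in kJ/mol at the series temperature
(298.15 K default; the reference tables evaluate at 298 K). [Q] is the
*total added* quencher concentration throughout — the titration is plotted
against added drug and no free-ligand correction is described for this
workflow; at the 1.5–16.5× drug:protein ratios of the design the distinction
is small but real, and is one known limitation.

**Point exclusion.** Instrument practice drops early titration points "to
obtain the best fit" without a stated rule. We use a deterministic one:
points with quench fraction (F₀−F)/F₀ < 2% are excluded (the difference
F₀−F is noise-dominated there and its logarithm blows up); exclusions are
recorded on the fit object. The threshold is configurable.

**Job plot.** At constant total T = [P]+[L], the complex concentration as a
function of the protein mole fraction χ peaks at χ = 1/(n+1) for an n:1
(ligand:protein) complex. χ is defined as the **protein** fraction — the
convention flips n to 1/n if reversed, so it is stated everywhere. The grid
argmax is refined by a least-squares parabola over ±2 grid points (exact
for the symmetric 1:1 case, robust on the 11–21 point grids typical of the
method); the continuous estimate n = (1−χmax)/χmax snaps to a small integer
ratio (1:1, 1:2, 2:1, 1:3, 3:1) when χmax is within 0.05 mole-fraction
units of the ratio's ideal position, and is otherwise reported unsnapped.

**Peak analytics.** λmax is the in-window global maximum, ties broken
toward the shorter wavelength, optionally refined by a 3-point parabola
(validated against dense-grid brute force to 0.1 nm for unimodal bands).
Δλ > 0 is classified bathochromic (red; increased microenvironment
polarity), Δλ < 0 hypsochromic (blue; increased hydrophobicity). EEM peaks
are picked per search region — defaults bracket the two canonical albumin
peaks, ex/em 220/345 (backbone+Trp) and 275/350 (Tyr/Trp) — after optional
masking of first/second-order Rayleigh ridges (|em − k·ex| < 12 nm,
k ∈ {1,2}; the half-width is two 5-nm excitation steps). Reduction percents
round to the nearest integer with halves away from zero; that rule, not
banker's rounding, reproduces the reference table (9.64→10, 8.84→9,
3.75→4).

## Synthetic data

The simulator emulates the reference design: protein at 2×10⁻⁶ M, quencher
0–33×10⁻⁶ M in 3×10⁻⁶ M steps, pH 7.4, 298.15 K; emission band centered at
338 nm; UV bands at 211 nm (strong, width 6 nm) and 280 nm (weak); EEM
grids ex 220–350 nm / em 220–500 nm at 5 nm; Job series at constant total
2×10⁻⁶ M. Titrations come in two modes: `stern_volmer` (intensities follow
the linear law exactly, with the quoted constant) and `equilibrium` (a 1:1
complex from the closed-form quadratic mass balance, the complex dark in
proportion to a quench efficiency in (0,1]). In the weak-binding limit
(K_b·[L]max ≪ 1) the two modes agree to first order, a property the tests
check. The quadratic is evaluated in the cancellation-free form
2·Pt·Lt/(b + √(b²−4·Pt·Lt)) and validated against a bisection oracle to
1e-10 relative over K_b ∈ [1, 10⁹], concentrations 10⁻⁹–10⁻³ M. Job series
with n ≥ 2 solve the single-step mass balance Kβ(Pt−x)(Lt−nx)ⁿ = x by
bracketed root finding, returning the saturating bound min(Pt, Lt/n)
directly when the residual does not change sign.

Noise is multiplicative Gaussian (sd proportional to signal), matching a
shot-noise-dominated photomultiplier readout; the generator takes no other
noise model. All draws come from a generator seeded by the ground-truth
record, so identical truth + design is bit-identical. Default noise in the
analysis drivers is 0.5% of signal — a clean bench fluorimeter; the
recovery study uses 1%.

What the simulator does **not** model: inner-filter attenuation (a
correction utility F·10^((A_ex+A_em)/2) exists but the generator emits
IFE-free intensities), lifetime/temperature dependence (single-temperature
study; no van't Hoff ΔH/ΔS), instrument response or wavelength calibration,
and competitive or multi-site binding. Passing tests therefore demonstrate
correctness of the inference chain under the stated models, not robustness
to those real-data artifacts.

## Numerical choices and edge cases

- OLS via `scipy.stats.linregress`; R² clipped into [0,1]; a perfect fit
  reports exactly 1. Standard errors are the usual OLS covariance values —
  no bootstrap, since the provenance of published ± figures is unstated.
- Degenerate inputs raise typed errors: fewer than 3 usable points
  (`FitDegenerateError`, CLI exit 3), invariant violations
  (`ValidationError`, CLI exit 2). A flat Job signal is degenerate; a flat
  spectrum resolves λmax to the shortest in-window wavelength by the tie
  rule.
- Parabolic refinements fall back to the grid argmax at window edges or
  when the local quadratic is not concave.
- CSV numbers are written with 17 significant digits, so round trips are
  exact to float64; concentration columns declare units (µM by default) and
  convert to mol/L on read.

## Design choices on genuinely open points

- **Readout wavelength for fits**: published workflows rarely state whether
  the titration readout is the λmax value or a fixed wavelength; both are
  supported, and the series records which was used (default: λmax of the
  drug-free spectrum, the field convention).
- **EEM molar ratios**: the design text and the result table disagree on
  the drug:protein ratios recorded (5:1/10:1 vs 2.5:1/5:1); the simulator
  takes the ratio as a free parameter and the analysis drivers follow the
  result table.
- **Full-precision arithmetic**: derived constants are reported at full
  precision rather than reproducing rounded intermediate values; e.g.
  2.64×10³/6.3×10⁻⁹ = 4.19×10¹¹ (tables print 4.18, consistent with
  dividing an unrounded slope), −RT·ln(63.67×10³) = −27.4 kJ/mol at 298 K
  (printed −27.3), and 60.73/2.64 = 23.0-fold (described as 22.3-fold).

## Known limitations

- The double-log intercept is an extrapolation to log₁₀[Q] = 0 from data
  spanning roughly [−5.5, −4.5]; slope noise is therefore amplified ~5× in
  log₁₀K_b. The recovery study shows this concretely: at 1% noise on the
  12-point design the strong-binder truth (log K_b = 4.80) is recovered
  with median 4.80, while the weak binder (4.14, where quench fractions are
  small and several points sit near the exclusion threshold) recovers with
  visible downward bias and wide spread. Weak-binder constants from this
  transform should be quoted with generous uncertainty.
- Problem sizes throughout (12-point titrations, 21-point Job grids,
  200-replicate recovery, 100-seed Job noise sweep) are the study's own
  design scales; they run in seconds.
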