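# Methods

`clampeq` implements the quantitative core of a thermodynamic analysis of
complexin (CPX) binding to assembled and half-zippered SNARE complexes:
binding-equilibrium algebra, isothermal titration calorimetry (ITC)
isotherm simulation and fitting, a self-association model mapping dynamic
light scattering (DLS) radii to oligomer size, and Förster resonance energy
transfer (FRET) distance determination from donor quenching. Synthetic-data
generators stand in for the three instruments, so every estimator in the
package can be exercised end-to-end against known ground truth.

## Binding equilibria

Two closed-form mass-balance problems underlie everything else.

**Heterodimerization.** For totals R (receptor) and L (ligand) forming a
1:1 complex with dissociation constant K_d, the complex concentration is
the physical root of [RL]² − (R+L+K_d)[RL] + RL = 0. We evaluate it in the
conjugate ("citardauq") form 2RL/(S + √(S² − 4RL)), S = R+L+K_d, which is
stable when RL ≪ S² — the regime of a tight binder in excess, exactly where
the naive root cancels catastrophically. Percent saturation at an x-fold
molar excess is 100·[RL]/R with L = xR. With R = 20 µM, K_d = 457 nM and a
1.5-fold excess this gives 95.9%; at 2.5–3-fold excess it gives 98.5–98.9%.
(A ≥99% figure sometimes quoted for the 2.5–3-fold condition corresponds to
a higher pre-dilution incubation concentration; both numbers appear in the
saturation report and neither is adjusted.)

**Self-association.** A species whose free pool obeys [free]² = K_d·[bound]
with [free]+[bound] = C has [free] = K_d(√(1+4C/K_d) − 1)/2. The bound
probability p = [bound]/C is evaluated as p = 4x/(1+√(1+4x))², x = C/K_d,
an algebraically identical form with no subtraction of near-equal terms;
the naive 1 − [free]/C loses ~8 significant digits at C ≪ K_d.

Thermodynamic conversions use ΔG = −RT ln K_a and TΔS = ΔH − ΔG with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and a default temperature of 298.15 K (the
calorimetry-software convention; all energies in kcal/mol). Temperature is
configurable on every parameter object.

## ITC: forward model

A titration is described by its cell volume V₀ (default 200 µL), initial
cell concentration M₀, syringe concentration X₀ and injection schedule
(default 20 × 2 µL, optionally preceded by a discarded 0.4 µL
pre-injection). After cumulative injected volume v, the standard perfusion
displacement correction gives the totals in the cell:

    Mt = M₀ (1 − v/2V₀)/(1 + v/2V₀),   Xt = X₀ (v/V₀)/(1 + v/2V₀).

This closed form tracks an explicit serial-mixing simulation to better than
0.5% over a 20% cell-volume turnover (tested).

The single-class-of-sites (Wiseman) cumulative heat is

    Q = n·Mt·ΔH·V₀/2 · [A − √(A² − 4Xt/(n·Mt))],
    A = 1 + Xt/(n·Mt) + 1/(n·K_a·Mt),

which equals V₀·ΔH·[bound] with [bound] from the n-site quadratic (the test
suite checks this equivalence against an independent bisection solver to
1e-8). Per-injection heats apply the displacement term
ΔQᵢ = Qᵢ + (dVᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2 − Qᵢ₋₁, and normalized heats (NDH) divide
by the moles of titrant in each injection.

**Two independent site classes.** For a bivalent titrant engaging two
non-interacting site classes (K₁, ΔH₁, n₁) and (K₂, ΔH₂, n₂), the free
titrant L after each injection solves

    Xt = L + Mt Σⱼ nⱼKⱼL/(1+KⱼL)

by bracketed root finding on [0, Xt] (the left side is strictly increasing
in L), and Q = V₀·Mt·Σⱼ nⱼΔHⱼKⱼL/(1+KⱼL). No polymer/cross-linking
correction is applied to the heats: independent site classes are the
simplest model that produces the multiphasic thermogram expected when both
partners are bivalent, and anything richer would not be identifiable from a
single titration. A class with ΔH = 0 or K_a = 0 is treated as absent, so
the model reduces exactly to the one-site isotherm in those limits; note
that a physically present site that merely happens to be calorimetrically
silent would still sequester ligand, a case this convention deliberately
ignores.

## ITC: fitting

`OneSiteBindingModel(thermogram, experiment).fit()` minimizes squared
residuals of normalized heats over (log K_a, ΔH, log n) with
Levenberg–Marquardt; the log parameterizations keep K_a and n positive
without imposing active bounds. Starting values: ΔH from the first retained
injection, n from the steepest-descent molar ratio, K_a from a curve-width
heuristic (the half-height width of a Wiseman sigmoid scales as c^−1/2,
c = n·K_a·M₀). Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹; K_d and n errors by the delta method from their logs. Derived
ΔG and TΔS are computed through the equilibria layer.

Identifiability follows the classic c-value rule. For c between ~5 and
~1000 the free three-parameter fit recovers generating parameters with
<2% bias at 1% noise (property-tested at c = 5, 50, 500). Outside roughly
1–1000 the results object carries a poorly-determined-affinity warning
(never an exception). For c below ~5 — the blocked-complex titrations here
have c ≈ 0.8–1.3 — the triple (n, ΔH, K_a) is degenerate: at 2% noise a
fraction of replicates converge to compensating extremes (small n, large
|ΔH|) that are genuine global optima of those noise draws. The standard
low-c protocol is therefore applied in the benchmark pipeline: n is held at
its known value of 1 (`fix_stoichiometry=1.0`) and only (K_a, ΔH) are
fitted. With that convention the replicate-mean K_d recovers the
generating value to well within the printed replicate uncertainties at all
four study geometries.

A six-parameter two-class fit (`TwoSiteBindingModel`) is provided for
completeness and verified for noise-free self-consistency; with a single
titration its parameters should be interpreted cautiously.

## DLS oligomerization model

CPX–SNAREΔ60 units carrying a free accessory helix can cross-link into
chains. Each cross-link is treated as an independent association with
dissociation constant K_d, so the engaged fraction p at total concentration
C follows the self-association quadratic above; the mean chain length is
N = 1/(1−p) (a geometric chain-length distribution with continuation
probability p), equivalently N = (1+√(1+4C/K_d))/2; and the observed
average radius is modelled as the gyration radius of an N-mer,
r = √N·r₀, with r₀ the inter-unit spacing (≈ monomer size). The √N scaling
is exact for long ideal chains and semi-quantitative for the small
oligomers (N ≈ 1–3) in the experimental window; measured DLS radii are
hydrodynamic rather than gyration radii, a conflation inherited by the
model and not corrected here. No intensity-weighting of the size
distribution is attempted.

`OligomerSizeModel(series).fit()` does least squares on radii over
(log K_d, r₀), weighted by per-point radius SDs when supplied; r₀ is
bounded to (0.5, 20) nm and K_d to at most 1 mM. The fitted K_d of a
5-point curve is right-skewed, so its replicate mean carries a systematic
upward bias of a few percent at 3% radius noise — within the 10% band used
for validation, but worth remembering when comparing small differences.
A fitted K_d at or above the largest sampled concentration means the
association never develops inside the measured range; the results flag
this as the low-affinity (non-specific aggregation) regime. Curves
generated at K_d = 250 µM over the 5–100 µM panel trigger the flag on
every replicate while still returning r₀ to within 10%.

## FRET

Efficiency is measured from donor quenching only (no sensitized-emission
ratioing): E = 1 − ∫F_DA/∫F_D, integrated trapezoidally over a wavelength
window covering the donor band (default 410–470 nm inside a 410–600 nm
scan, configurable). Spectra must share a wavelength grid inside the
window; silent resampling is refused. The distance follows from the
Förster relation r = R₀(1/E − 1)^(1/6), with R₀ the 50%-efficiency
distance of the dye pair (≈27 Å for stilbene/bimane, ≈38 Å for
bimane/Oregon Green). An optional labeling-efficiency correction
E/f_label is available and off by default (labeling was >95% in the
emulated experiments). E→r is a bijection on (0,1), round-trip-stable to
1e-10 (tested over E ∈ [0.01, 0.99]).

## Synthetic data

Generators emulate the statistical structure of each instrument's output,
not its raw signal chain:

- **ITC** (`gen_itc`): forward-simulated thermograms plus additive Gaussian
  noise on normalized heats with sd = noise_fraction·|ΔH| (default 2%, the
  dominant error of integrated injection peaks). No baseline drift,
  heat-of-dilution blanks or injection-volume errors are simulated.
- **DLS** (`gen_dls`): model radii with multiplicative Gaussian noise
  (default 3%), over a default panel of 5, 10, 25, 50, 100 µM spanning the
  oligomerization onset. No autocorrelation-function or regularization
  artefacts.
- **Spectra** (`gen_spectra`): a Gaussian donor band (centre 440 nm,
  sd 18 nm) on a 1-nm grid, with the donor–acceptor trace scaled by (1−E);
  additive detector-like noise. No acceptor emission bleed-through or
  photobleaching.

Each call derives its random stream from (seed, operation name), so
generators are mutually independent and reproducible. Passing tests on
these generators demonstrates estimator correctness and statistical
calibration under the stated noise models — not robustness to the
systematic errors (baseline handling, concentration mis-measurement,
polydispersity, spectral overlap) real instruments add.

## Problem sizes and numerical choices

Validation uses 50 replicates per recovery benchmark (20-injection
thermograms; 5-point DLS curves), matching the scale at which the
replicate means stabilize; the full suite runs in a few seconds. Root
finding uses machine-tolerance brentq on guaranteed brackets; optimizer
tolerances are 1e-12 (LM) and 1e-14 (bounded TRF); noise-free
self-consistency is asserted at 1e-6 relative. Degenerate inputs (zero
totals, zero donor signal, E at 0 or 1, fewer than 6 injections or 4 DLS
points) raise typed errors rather than propagating NaNs; diagnostic
conditions (poor c-value, aggregation regime) are warnings on the results
object and never change exit codes.
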