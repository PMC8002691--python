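# Methods

## Isotope arithmetic

All conversions run through delta notation: R = (δ/1000 + 1)·R_ref and the
atom fraction R/(1+R). The labelled amount of a bottle's N₂O is
¹⁵N₂O = N₂O·R/(1+R) with N₂O expressed in nmol of N atoms, matching the
units of the instrument detection limit (1.0 nmol N). Bulk δ¹⁵N treats the
two nitrogen positions of N₂O as exchangeable; site preference and
isotopomers are out of scope. The working-gas ratio R_ref and the
atmospheric ratio R_air both default to 0.0036765 (AIR), the universal
δ¹⁵N reference; both are configurable and the choice of R_ref cancels in
any quantity that round-trips through the same constant. The delta domain
is open below at −1000‰ (zero ¹⁵N); conversions reject values at or below
it. The inverse conversion (labelled amount → δ) is exact, which is what
lets the simulator construct observations whose noise-free fit returns the
generating rate to floating-point precision.

The substrate label fraction f¹⁵ is the amount-weighted mean of tracer
purity and ambient natural abundance. The ambient pool is
concentration × liquid volume; concentrations at or below the analytical
detection limits (0.2 µmol L⁻¹ for NO₃⁻, 15 nmol L⁻¹ for NH₄⁺) are
treated as zero with a logged warning, since a value below detection
carries no usable information about the pool size. Whether the ambient
pool is included at all is a config switch (`f15_includes_ambient`,
default true): with a ~25 µM nitrate pool against ~4 µM of added tracer
the distinction matters a factor of ~7 in f¹⁵, and both conventions occur
in practice. The ambient pool is assumed to sit at natural abundance
(δ = 0‰ vs. AIR) absent a measured ambient δ¹⁵N.

## Rate estimation

Rates are volumetric: the regression runs on whole-bottle ¹⁵N₂O amounts
(nmol ¹⁵N) against time in hours, and R = slope·24/(f¹⁵·V) yields
nmol N L⁻¹ d⁻¹ with V = 0.118 L (120 mL serum bottle minus 2 mL helium
headspace). Ordinary least squares is used for ≥3 time points (slope
standard error and a one-sided p-value for slope > 0 are reported); a
two-point endpoint design yields the exact difference quotient with no
uncertainty estimate rather than being rejected, because endpoint-only
sampling is a legitimate and common design. Measurements whose N₂O
quantity falls below the detection limit are flagged and excluded from the
regression but retained for reporting; a series left with fewer than two
usable points is an estimation error, not a silent zero. Negative fitted
rates are preserved in `rates.csv` (they are informative about noise) and
floored at zero, with a flag, only when entering the source partition. No
multiple-testing correction is applied across depths; the per-depth
p-values are descriptive.

## Source partitioning and its interpretation

fungal = rate under chloramphenicol; bacterial = total − fungal, clamped
at zero (flagged) when the inhibited rate exceeds the uninhibited one;
nitrification = the ¹⁵NH₄⁺ rate, carried alongside but not part of the
NO₃⁻-derived budget. Chloramphenicol blocks prokaryotic protein synthesis
rather than instantly stopping existing enzymes, so the inhibited rate can
include residual bacterial activity: the fungal rate is an upper limit.
The simulator encodes this directly as `cap_leakage_fraction` — the
fraction of the bacterial rate that survives inhibition (default 0) — and
the recovery experiments show that a 30% leakage inflates the recovered
"fungal" fraction well above the generating truth, which is precisely why
the partition should be read as a ceiling.

When the partition holds (no clamp), fungal + bacterial re-sums to the
reported total exactly in floating point; the total is stored as that sum,
which can move it by one ulp relative to the fitted input.

## Interface finding and depth integration

The oxic–anoxic interface is the shallowest depth where O₂ first falls
below a threshold, linearly interpolated between the bracketing samples;
the default threshold is 1.0 µM, within the sub-micromolar band where
denitrification switches on and near the floor of shipboard O₂ sensors,
and is configurable because that floor is instrument-dependent. A profile
that never crosses the threshold is an error, not an extrapolation.

Fungal and total NO₃⁻-derived rates are integrated over depth by the
trapezoidal rule, with linear interpolation onto the integration bounds;
bounds outside the sampled depth range are refused. Units convert
one-to-one: nmol N L⁻¹ d⁻¹ integrated over metres is µmol N m⁻² d⁻¹. The
fungal fraction is the ratio of the two integrals × 100. The trapezoid is
exact for the piecewise-linear profiles the sampled data define, which is
what the fine-grid oracle in the tests verifies.

## The synthetic study

Each station is a scenario: a sampling grid, a sigmoidal oxycline
O₂(z) = O₂_surface/(1 + exp((z − z_c)/w)), a linear ambient nitrate
profile, and three pathways with O₂-inhibition R(O₂) = R_max·exp(−O₂/k).
Defaults (units µM for k, nmol N L⁻¹ d⁻¹ for R_max): bacterial
denitrification k = 0.5 (strongly inhibited — consistent with repression
by sub-micromolar O₂), fungal k = 2.0 (less inhibited, opening a suboxic
niche where the fungal share of NO₃⁻-derived N₂O rises), nitrification
k = 30 (weakly inhibited). Peak rates of ~40 nmol N L⁻¹ d⁻¹
(≈20 nM N₂O d⁻¹) reflect *potential* rates under substrate amendment —
bottles receive ~4 µM extra nitrate — and sit at the upper end of, but
within, observed OMZ interface ranges. Fungal R_max values (1.2167015 and
1.1306701) are fixed so that each default station's true depth-integrated
fungal fraction, computed on its own sampling grid with the same interface
criterion and trapezoid as the analysis, is exactly 20.0%; defining truth
through the discretised pipeline means recovery experiments measure
measurement noise, not grid discretisation.

Station 1 samples 60–120 m (oxycline top 60 m, interface ≈93.6 m) with
endpoint-only bottles at 0 and 24 h; Station 2 samples 90–275 m (top 90 m,
interface ≈126.7 m) at 0, 12 and 24 h. Each depth gets one bottle per
treatment per time point.

Observation model: the whole-bottle N₂O pool starts from a 50 nM
background (≈11.8 nmol N per bottle) at δ¹⁵N = 0‰ and grows linearly at
the treatment's labelled-substrate rate; the labelled amount grows at
f¹⁵ times that. Observed quantities are multiplied by mean-1 lognormal
noise (cv 0.02 — an assumed, not instrument-quoted, figure for
purge-and-trap quantification); observed δ¹⁵N gets additive Gaussian noise
with σ = 2.0‰, the quoted instrument precision. Produced N₂O is assigned
the substrate pool's atom fraction outright (no binomial isotope pairing)
because the estimator uses bulk ¹⁵N only, and substrate drawdown over 24 h
is neglected (tracer excess over one day). Every simulated series draws
from its own seeded generator spawned from the study seed; identical
seeds give byte-identical tables.

What the generator does **not** emulate: bottle effects and regime shifts
over the incubation, N₂O consumption (reduction to N₂), hybrid/abiotic
N₂O formation, real replicate structure, or spatial patchiness. Passing
recovery tests therefore demonstrates that the estimator chain is correct
and well-behaved under the assumed noise — not that field data meet those
assumptions.

## Known biases and limitations

The recovery experiments expose a real property of the method, not a bug:
clamping (CAP > total) and flooring of negative fitted rates make the
integrands non-negative, so over the upper oxycline — where true rates are
essentially zero but fitted rates scatter around zero — both depth
integrals accumulate a positive noise floor, and the small fungal integral
inflates proportionally more. With the default noise this biases the
median recovered fungal fraction ~2–3 percentage points above the 20%
truth (single seeds scatter several points around that). The bias shrinks
with the extent of near-zero water column inside the integration window
and with the signal-to-noise of the rates; it would vanish if negative
rates were carried through the integrals, but zero-floored rates are the
field convention (reported shares are bounded at 0%) and are kept. Readers
of single-campaign results should expect small integrated fractions to be
upper-biased for this reason, independent of the chloramphenicol-leakage
ceiling discussed above.

The gene-detectability model is read-level: a read "hits" a gene of
length L in a genome of size G with probability L/G (optionally
(L + read_length − 1)/G to count any overlap), giving a Poisson expected
count λ and P(≥1) = 1 − e^(−λ). It assumes one fungal genome at the given
read fraction and ignores mapping sensitivity and database completeness —
all simplifications that make the answer an upper bound on detectability,
which strengthens rather than weakens the conclusion that absence at
λ ≪ 1 is uninformative. The default genome (30 Mb) and gene (1.5 kb)
sizes are typical figures, config-exposed.

## Problem sizes

The validation suite uses 1000 replicate bottles for the rate-recovery
Monte Carlo, 100 simulated campaigns per station for fraction recovery
(30 for the leakage comparison), 100–200 random cases per numerical
oracle, and 1 cm grids for integration oracles. These sizes give medians
and biases stable to well under the tolerances they are checked against.
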