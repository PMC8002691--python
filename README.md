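# tracern2o

Estimation and source partitioning of nitrous-oxide (N₂O) production rates
in oxygen-minimum-zone (OMZ) water columns from ¹⁵N-tracer bottle
incubations, with a chloramphenicol selective-inhibition split into fungal,
bacterial and nitrification sources and a depth-integrated fungal
contribution. Written for isotope biogeochemists who run (or want to plan)
tracer incubation campaigns, and shipped with a synthetic-experiment
generator so the entire analysis runs and can be validated without any
field data.

## The method

An incubation bottle receives ¹⁵N-labelled substrate (nitrate or ammonium)
so that the substrate pool has atom fraction

    f¹⁵ = (n_tracer·purity + n_ambient·f_nat) / (n_tracer + n_ambient),

where the ambient pool sits at natural abundance f_nat = R_air/(1+R_air).
At each time point the mass spectrometer reports the bottle's N₂O quantity
(nmol N) and its bulk δ¹⁵N (‰ vs. a reference gas of ratio R_ref). The
labelled portion is

    ¹⁵N₂O = N₂O · R/(1+R),   R = (δ¹⁵N/1000 + 1)·R_ref,

and the volumetric production rate follows from the slope of ¹⁵N₂O against
time (ordinary least squares; a difference quotient for two-point endpoint
designs):

    R_N₂O = (d¹⁵N₂O/dt) / (f¹⁵ · V)        [nmol N L⁻¹ d⁻¹]

with V the incubation liquid volume (0.118 L: a 120 mL bottle minus a 2 mL
helium headspace). Points below the 1.0 nmol N detection limit are
censored; δ¹⁵N precision is 2.0‰.

Source attribution uses parallel treatments at every depth: ¹⁵NO₃⁻ alone
(total denitrification-derived N₂O), ¹⁵NO₃⁻ + chloramphenicol (prokaryotic
protein synthesis inhibited, so the residual rate is an upper limit on
fungal denitrification), and ¹⁵NH₄⁺ (nitrification). Per depth:
fungal = CAP rate, bacterial = total − fungal (clamped at 0 and flagged if
negative). Fungal and total rates are then integrated over depth by the
trapezoidal rule from the top of the oxycline to the oxic–anoxic interface
(the interpolated depth where O₂ first drops below 1 µM), giving the
fungal percentage of NO₃⁻-derived N₂O production.

Two auxiliary pieces:

* **Synthetic experiments** — per-pathway rates decline with in-situ O₂ as
  R(O₂) = R_max·exp(−O₂/k_O₂), with fungal denitrification less
  O₂-sensitive than bacterial; bottle observations carry lognormal quantity
  noise and Gaussian δ noise. The default two-station design has a true
  integrated fungal fraction of exactly 20%.
* **Gene detectability** — expected fungal *P450nor* reads in a metagenome,
  λ = reads · fungal_fraction · gene_length/genome_size, and
  P(≥1 read) = 1 − e^(−λ) under Poisson sampling.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each is a thin driver over the `tracern2o` library):

```bash
python analysis/01_simulate.py --seed 1   # bottles + depth profiles
python analysis/02_fit_rates.py           # rates per (depth, treatment)
python analysis/03_partition.py           # fungal / bacterial / nitrification
python analysis/04_integrate.py           # depth-integrated fungal fraction
python analysis/05_report.py              # results/report.md
python analysis/06_detectability.py       # P450nor sequencing-depth table
```

With seed 1 this prints (abridged):

```
Station1: ... true integrated fungal fraction 20.00% between 60 m and the interface at 93.6 m
Station2: ... true integrated fungal fraction 20.00% between 90 m and the interface at 126.7 m
fitted 60 series (0 excluded)
Station1: NO3-derived rates span 0.00 to 40.84 nmol N L^-1 d^-1
partitioned 20 depths (4 clamped, 5 floored)
Station1: fungi account for 26.4% of NO3-derived N2O production over 60-93.6 m (truth 20.0%)
Station2: fungi account for 23.4% of NO3-derived N2O production over 90-126.7 m (truth 20.0%)
```

Rates peak at the oxic–anoxic interface and the single-seed recovered
fungal fractions scatter around the generating 20% (clamping and flooring
of noisy near-zero rates push single runs a few points high; see
`docs/methods.md`). The detectability table shows an expected 0.1
*P450nor* reads in a 10⁷-read metagenome at a 0.02% fungal read fraction —
absence of the gene at realistic sequencing depth is uninformative.

The same stages are available as a CLI
(`tracern2o simulate|fit-rates|partition|integrate|detectability|report`)
for use on real tables; input/output CSV schemas are documented in
`tracern2o.io`, and `examples/` holds a run-config and a scenario YAML.

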