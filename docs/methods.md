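# Methods

## Stoichiometry model

The package treats a colloidal suspension as a closed excipient budget: all
of the excipient put into the formulation resides in particles, so

- molecules/mL: `N = c · N_A / 1000` for molar concentration `c` (mol/L),
  with `N_A = 6.02214076e23` exactly;
- molecules/particle: `n = N / C_p` with `C_p` the counted particles/mL;
- particle molarity: `C_p · 1000 / N_A` (mol/L of particles).

Mass-fraction input (`%` w/v) converts as `10 · x / MW`. For cetyl
palmitate `MW = 480.85 g/mol`, so 10% w/v ↦ 208 mmol/L.

For a formulation quoted as a lipid:cholesterol mixture at a single molar
concentration, the stoichiometry is computed for the phospholipid alone —
cholesterol intercalates but the headgroup-area budget below is a
phospholipid property. This is a convention, exposed through
`FormulationSpec.excipient_name`.

The geometric counterpart for unilamellar vesicles divides both leaflets'
sphere area by the area per headgroup:
`n_geom = leaflets · π d² / a_L` with `d` in Å and `a_L = 55 Å²` by default
(configurable per lipid). Vesicles are assumed unilamellar (`leaflets = 2`);
no inner-leaflet radius correction for bilayer thickness is applied — at
~100 nm the correction is ~5% and smaller than counting error. Encapsulation
and drug loading are out of scope.

## Dispersity statistics

NTA-style statistics are number-weighted: D10/D50/D90 by linear
interpolation on the midpoint-convention cumulative distribution (ties by
stable sort), `Span = (D90 − D10)/D50`. DLS-style statistics are
intensity-weighted with the Rayleigh `d⁶` proxy:
`z = Σn·d⁶ / Σn·d⁵`, and PDI from cumulant-style moments of the decay-rate
distribution (`Γ ∝ 1/d`, intensity-averaged): `PDI = μ₂/Γ̄²`. PDI is zero
iff monodisperse, and both PDI and Span are scale-invariant. The d⁶ proxy is
applied at all sizes, including the micron range where Mie scattering
actually governs; this keeps the model analytic and only strengthens the
qualitative DLS-above-NTA ordering the analysis relies on. A sample is
classed monodisperse iff `PDI < 0.2` and `Span < 1` (the conventional
limits, strict inequalities).

## Stability analysis

Correlation is the sample Pearson r of per-condition mean size vs mean
concentration; `n` is the number of conditions (typically 4–5), so no
p-value is attached by default (available behind a flag). Verdicts compare a
condition to the series baseline with default 10% thresholds (the
literature offers no canonical value; 10% exceeds typical instrument
repeatability and both thresholds are configurable): concentration drop
beyond threshold with size rise beyond threshold ⇒ fusion/aggregation;
concentration drop without size rise ⇒ degradation; otherwise stable.
Thresholds are strict, so boundary cases fall in the milder class. The
conservation audit multiplies a per-condition molecules/particle value
(externally supplied, e.g. a published table column) by the counted
particles/mL and flags deviations from the formulation total beyond a
tolerance — with the rounding of printed tables, 2% (liposome series) and
5% (SLN series) are the observed consistency bands.

## Synthetic colloids

Populations are explicit diameter lists (lognormal mixtures;
`(median, geometric SD, weight)` per mode) in a known suspension volume.
Vesicle operators conserve `Σd²` (lipid lives in the shell; membrane area ∝
lipid count) and solid operators conserve `Σd³` (excipient fills the core);
consequently `C_p × mean(n)` is invariant under every operator — the
simulated analogue of the audit above.

- **Extrusion**: per passage, a vesicle with `m = round(d²/pore²) ≥ 2`
  fragments into `m` daughters drawn around the pore size (geometric jitter,
  default GSD 1.10; equal-daughter dialect available) and rescaled to the
  parent's `d²`. Rounding the fragment count keeps daughters within ~15% of
  the pore, so vesicles barely above the pore squeeze through intact —
  consistent with extruded formulations measuring at or somewhat above the
  pore size. An optional per-passage fragmentation `efficiency` (default 1)
  spreads break-up over passages, reproducing the gradual passage-by-passage
  size decrease of a bench extruder; the analysis driver uses 0.7.
- **Fusion** (solvent destabilization): per round, a chosen fraction of
  disjoint random pairs merges with `d = √(d₁² + d₂²)`.
- **Aggregation** (surfactant depletion, solid particles): merge propensity
  `p = 1 − f^γ` for coverage fraction `f` (γ = 2 default). Particles are
  randomly partitioned into clusters with geometric(1 − p) sizes — expected
  cluster size `1/(1 − p)`, a heavy tail as real agglutination shows — and
  each cluster collapses to `(Σd³)^{1/3}`. The coverage→propensity map is
  illustrative, not fitted to any measured series.

All operators are deterministic given a seed.

## Instrument forward models

**NTA**: with diluted concentration `c/D` and sampling volume `V` (default
`1e-7` mL, putting bench-scale concentrations at bench-scale dilutions in
the instrument's working range of tens to hundreds of particles in view),
the total occupancy over `F` frames is Poisson(`c/D · V · F`)
particle-frames, partitioned into tracks with geometric length distribution
(mean 30 frames; tracks under 10 frames are excluded from sizing but still
occupy frames). Each track's per-axis steps are Normal(0, √(2DΔt)) with
`D = k_B T / (3πηd)` (water at 25 °C: T = 298.15 K, η = 8.9e-4 Pa·s;
Δt = 1/30 s). Sizing uses the lag-1 MSD estimator
`D̂ = Σ(Δx² + Δy²)/(4nΔt)` inverted through Stokes–Einstein — chosen for
transparency over covariance estimators, and swappable. No finite-track-
length bias correction is applied; at the default track lengths the median
bias is ~1%. Concentration is mean particles per frame / V × dilution,
which is exact Poisson counting by construction. Localization noise is off
by default (no imaging parameters are modelled).

**DLS**: the population's z-average and PDI (above), each optionally
multiplied by `1 + ε`, `ε ~ N(0, noise_sd)`.

## What the generator does and does not emulate

It reproduces the structural phenomenology the analysis must detect:
number-vs-intensity weighting contrasts, excipient-conserving
fragmentation/merging, count-vs-size anticorrelation under destabilization,
and Poisson counting statistics. It does not emulate multilamellarity (real
non-extruded liposomes hold lipid in many shells, so real extrusion
multiplies particle count far less than area conservation implies),
non-sphericity, Mie scattering, inter-particle interactions, or video-level
NTA artefacts (drift, vibration, mis-tracking). Passing tests therefore
demonstrate the pipeline's correctness on idealized colloids, not
instrument-level accuracy on real samples.

## Problem sizes and numerical choices

Simulated populations of 3 000–6 000 particles and ~40 instrument replicates
give sub-percent Monte-Carlo error on every asserted summary while keeping
the full suite and the acceptance script fast. Conservation checks use
relative tolerance 1e-6 (operators are exact to rounding); Stokes–Einstein
round-trips to 1e-12. Degenerate inputs (empty populations, zero counts,
constant series) raise typed errors rather than returning NaN. Stochastic
checks on 95% intervals are asserted as coverage over many seeds against a
binomial bound, not as a single draw, since one seeded draw fails 1 time
in 20 by design.

## Known limitations

- The Pearson r of a 4–5 point series is a descriptive statistic; its
  sampling error is large and no inference is offered by default.
- The printed-table audit inherits the tables' 2-significant-figure
  rounding; deviations below ~2% are not meaningful there.
- The aggregation coverage→propensity law is a one-parameter stand-in for
  DLVO-style kinetics; only its monotonicity is load-bearing.
- NTA size estimates carry the usual small-track-length positive skew;
  medians are used where robustness matters.
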