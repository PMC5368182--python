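# Methods

## Scope and model overview

`rrnthermo` analyses intragenomic heterogeneity of 16S rRNA genes in
prokaryotes that carry several divergent rRNA operons, with the halophilic
archaeon *Haloarcula hispanica* (paralogs *rrsA*, *rrsB*, *rrsC*) as the
reference system. Three observation channels are modelled:

1. **Sequence channel** — the GC content (P_GC) of a primer-bounded 16S
   region is an empirical "molecular thermometer" for the host's cardinal
   growth temperatures.
2. **Expression channel** — reverse-transcription qPCR with paralog-specific
   primers measures the expression ratio of the high-GC paralog (*rrsA*) to
   the near-identical low-GC pair (*rrsBC*) across culture temperatures.
3. **Growth channel** — OD₆₆₀ time courses converted to cell densities yield
   interval growth rates and the cardinal temperatures actually realised.

## Primer matching and region extraction

Primers are stored 5′→3′ as synthesised; reverse primers are matched through
their reverse complement. A template position matches a primer position when
the two bases' IUPAC sets intersect, which reproduces wet-lab annealing
semantics for degenerate primers (e.g. 109aF `AMD GCT CAG TAA CAC GT`) and is
permissive for template ambiguity codes. The best site minimises mismatches,
ties resolve leftmost, and a strict-uniqueness mode turns ties into errors.
The default mismatch budget is 0.

Coordinates are 1-based inclusive. A primer pair delimits a region **inclusive
of both primer binding sites**: 109aF (83–99) with 915aR (858–877) gives the
795 bp thermometer region (877 − 83 + 1), and 8aF (3–18) with 1512uR
(1424–1442) the 1440 bp near-full-length gene. The inclusive convention is
forced by those printed lengths even though "between the primers" naively
suggests exclusion; it is asserted by tests.

## GC content and pairwise identity

P_GC = 100 · (G + C + S) / (A + C + G + T + S + W). S is definitely G/C and W
definitely A/T; every other ambiguity code straddles the GC/AT split and is
excluded from numerator and denominator alike, making the statistic an
unbiased estimate of the underlying GC fraction. An all-ambiguous sequence is
an error, not 0.

Pairwise identity uses a global end-to-end alignment (match +1, mismatch −1,
gap open −2, gap extend −0.5 — defaults chosen for rRNA-scale similarity, all
configurable) and divides identical columns by the full alignment length;
per-sequence-length denominators are selectable. Divergent pairs admit
co-optimal alignments whose enumeration order depends on argument order, so
the pair is canonicalised (lexicographically) before aligning to make the
reported identity exactly symmetric. On indel-free pairs the result equals
the Hamming closed form (L − k)/L · 100, which the tests use as an oracle.

## The thermometer

For each cardinal temperature c ∈ {min, opt, max} a line T_c = slope_c · P_GC
+ intercept_c is fitted by ordinary least squares (the interpolating line when
exactly two points are given). The shipped default calibration uses the
published per-paralog reference rows for *H. hispanica* JCM8911:

| paralog | P_GC (%) | T_min (°C) | T_opt (°C) | T_max (°C) |
|---------|----------|------------|------------|------------|
| rrsA    | 58.9     | 32.6 ± 16.7 | 51.6 ± 11.8 | 59.7 ± 13.1 |
| rrsB    | 56.5     | 22.2 ± 16.4 | 39.8 ± 11.6 | 48.1 ± 12.8 |
| rrsC    | 56.4     | 21.7 ± 16.4 | 39.3 ± 11.5 | 47.6 ± 12.8 |

The three rows are collinear to within 0.1 °C, so a linear model in P_GC
alone is adequate; the recovered coefficients (e.g. slope ≈ 4.36 °C per %GC
for T_min on the two extreme rows) are a calibration of this package, not a
claim about the thermometer's originally published equations, which users can
substitute via a YAML model file. Uncertainty half-widths have no available
closed form here; they are linearly interpolated between the printed anchors
and clamped outside the anchors' P_GC range — an approximation, flagged as
such. Predictions more than a configurable margin (default 5 %GC) outside
the calibration range carry an `extrapolated` flag. Temperatures are reported
to 1 decimal; test comparisons allow ±0.2 °C to absorb the rounding of the
printed calibration inputs.

## qPCR quantification

Standard curves are least squares of mean Ct per dilution against
log10(dilution) (per-well fitting selectable), requiring ≥3 distinct detected
dilutions and a negative slope. Efficiency = 10^(−1/slope) − 1. Unknown wells
are back-calculated as quantity = 10^((Ct − intercept)/slope); quantities are
relative (dilutions of PCR product), which cancels in the ratio. Technical
replicates are averaged on the quantity scale before the per-biological-
replicate ratio is formed (Ct-scale averaging is selectable); the summary is
mean ± sd over biological replicates. Not-detected wells are excluded with a
warning, never imputed; a biological replicate missing a target entirely is
dropped with a warning. ΔΔCt analysis is deliberately absent — the
dilution-series design calls for standard-curve quantification.

Group comparison is a two-sided two-sample t-test, pooled-variance by default
with the Welch variant selectable (sidedness/variance assumptions are a
convention of this package). Two identical zero-variance groups return
t = 0, p = 1 by convention.

## Growth analysis

The cell-number factor (cells ml⁻¹ per OD₆₆₀; default 2.1 × 10⁹ for
*H. hispanica*) comes from a least-squares through-origin fit of microscopy
counts against OD. Interval rates use μ = (ln N₂ − ln N₁)/(t₂ − t₁); the
factor cancels inside the log ratio, which is kept as a tested invariant.
mu_max is the maximum interval rate (a regression-free estimator mirroring
the interval formula); negative rates are retained in profiles but only
selected when every interval is negative. Intervals touching a zero density
are flagged gaps.

Cardinal temperatures are restricted to the tested grid (25–50 °C in 5 °C
steps in the default design): T_opt is the argmax of mean mu_max with ties
resolved to the lower temperature, T_min/T_max the extreme temperatures whose
mean mu_max exceeds the growth threshold (default 0.005 h⁻¹, well below the
slowest observable growth; configurable). Raising the threshold can only
narrow the called range.

## Synthetic data

Generators are deterministic functions of (config, seed) via
`numpy.random.default_rng`; identical seeds give byte-identical output.

**16S family.** A random template (fill GC 57 %) is stamped with one concrete
expansion of each default primer at its canonical site (8aF@3, 109aF@83,
915aR@858, 1512uR@1424). The template's thermometer region is first anchored
to the least-divergent paralog's GC target; each paralog then receives
(a) GC-adjusting flips confined to free (non-primer) region positions that
set its region G+C count to round(target · 795), exact to one base
(±0.07 %GC), and (b) GC-neutral substitutions (A↔T, G↔C) topping total
changes up to round(divergence · length). Flips therefore count toward
divergence, and the defaults (0.054 / 0 / 0.004 with region GC
58.9/56.5/56.4 %) reproduce both the GC offsets and the ≈94.6 %/99.6 %
pairwise identities of the reference system. The generator makes no claim to
evolutionary realism (no rate heterogeneity, all top-up changes are
GC-neutral transversion-like swaps, no secondary-structure constraints).

**qPCR plates.** Ct = intercept + slope · log10(copies) + N(0, sd), with
slope −3.32 (≈100 % efficiency), intercept 35 cycles (arbitrary plumbing —
only Ct differences matter), noise sd 0.15 cycles, 3 technical × 4 biological
replicates, and a 1/10…1/10000 dilution series of a standard stock (default
10⁷ copies) so that standards bracket the unknown wells (5.6 × 10⁵ / 10⁶
copies, true ratio 0.56) and quantification interpolates. Gaussian noise on
the cycle scale is standard qPCR practice.

**Growth curves.** Flat lag (default 8 h), *pure* exponential growth at the
per-temperature rate, then logistic saturation once OD passes a switch
fraction (default 0.5) of carrying capacity (1.2 OD) — the pure-exponential
window makes the interval estimator exact on noiseless curves. Observed OD is
the true OD times a lognormal factor (σ = 0.01 by default). The default grid
puts μ = 0.02/0.05/0.09/0.13/0.16/0.10 h⁻¹ at 25/30/35/40/45/50 °C, peaking
at the 0.16 h⁻¹ optimum; sampling every 4 h runs until exponential growth
would reach capacity, plus two points.

**OD/count pairs.** Uniform OD in [0.05, 1.0] with counts = factor · OD ·
lognormal(0, cv), default factor 2.1 × 10⁹ and cv 0.05.

Because the generators implement exactly the statistical structure the
analysis assumes (log-linear Ct, exponential growth windows, through-origin
counts), passing recovery tests demonstrates correctness of the estimators
under the stated model, not robustness to the failure modes of real data
(pipetting gradients, plate effects, condensation, lysis, non-exponential
transitions).

## Numerical and design choices

* Region GC targeting is integer-constrained; the ±0.2 %GC acceptance window
  in tests is far wider than the ±0.07 attainable error.
* Monte-Carlo sizes (100 qPCR seeds, 20 growth seeds, 50 count-pair seeds)
  keep the whole suite in a few seconds while leaving comfortable margins on
  the recovery tolerances.
* The expression-ratio sd across simulated plates is validated against a
  delta-method propagation (Ct noise through curve-fit variance at the
  unknowns' lever arm) within a factor 1.5.
* The `replay` pipeline derives one child seed per stage from the global seed
  via `numpy.random.SeedSequence.spawn`, so stage outputs are individually
  reproducible and byte-stable per seed; its per-temperature true-ratio
  presets (0.56, 0.56, 0.80, 1.00, 1.30, 1.50) rise with temperature the way
  the measured ratios do, with cold-range values below 1 and hot-range values
  above.

## Known limitations

* Uncertainty half-widths are interpolated anchors, not prediction intervals.
* The thermometer coefficients are recovered from three collinear calibration
  rows; slopes are well-determined only inside 56–59 %GC and extrapolation is
  flagged, not prevented.
* Cardinal temperatures are grid-restricted by design; no Ratkowsky-style
  mechanistic model is fitted.
* Identity conventions differ between alignment tools; values within ~0.1 of
  a point are convention-sensitive for divergent pairs.
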