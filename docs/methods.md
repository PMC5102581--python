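# Methods

## Scope and model

`biocogs` computes the cost of goods per gram (CoG/g) of purified uricase
for three bioprocess routes at a fixed production scale — a 25 L *E. coli*
fermentation at a base titer of 0.484 g/L, held to a constant annual target
output — and analyses how that cost responds to parameter uncertainty.
The routes are:

* **chromatography** — centrifugation, high-pressure homogenization,
  centrifugation, three sequential chromatography columns, UF/DF;
  composite downstream (DSP) yield 43.2%;
* **atps** — the columns replaced by a single PEG2000/ammonium-sulfate
  aqueous two-phase extraction; DSP yield 66%;
* **atps_recycle** — the ATPS route with a back-extraction (second ATPS)
  that returns 60% of the PEG and 20% of each salt to the next batch.

Unit operations are economic abstractions only: a step recovery yield, a
stream volume factor, and cost attachments. No fermentation kinetics,
partition thermodynamics or equipment-level engineering is modelled.
Polishing operations (viral inactivation, nucleic-acid removal), PEGylation,
formulation and business factors (pricing, NPV) are out of scope.

## Cost engine

Annual cost is a fixed + per-batch-variable structure over five categories:

    annual = capital + other + labor + B x (materials/batch + consumables/batch)
    B      = target_output / (V x titer x dsp_yield)        (fractional batches)
    CoG/g  = annual / annual_mass,  annual_mass = B x V x titer x dsp_yield

Capital and "other" are annual fixed costs; labor is a four-role wage table
(production operator, production supervisor, QA, QC; UK/Mexico/USA) times a
headcount equivalent; materials and consumables are per-batch dollar lines.
UF/DF filter consumables are volume-driven: `ceil(feed_volume / capacity)`
filters per batch, where the feed volume comes from propagating stream
volumes through the flowsheet. Batches default to fractional (continuous
scheduling) so the response surface is smooth for the Monte Carlo and
surrogate analyses; an integer mode exists.

### Calibration

The engine is calibrated, not built bottom-up: only base-case CoG/g totals
($9,396.97 chromatography, $5,452.00 ATPS), a 13% labor share and the
qualitative category ordering (ATPS spends more on materials, less on
everything else) are externally anchored. `calibrate_fixture` takes a
target CoG/g and a per-category share vector and solves the fixed costs,
the labor headcount equivalent, and residual "other materials"/"other
consumables" lines exactly; infeasible share vectors (named lines exceeding
their category budget) raise a diagnostic error. The packaged share
vectors — chromatography (capital 0.32, materials 0.10, consumables 0.25,
labor 0.13, other 0.20) and ATPS (0.25, 0.30, 0.18, 0.13, 0.14) — are this
package's own choices consistent with that ordering, as are the named
per-batch lines: fermentation media $1,800 (both routes), PEG2000 $3,600,
ammonium sulfate $1,100, NaCl $300 (ATPS), and UF/DF filters at $1,100 each
with 50 L capacity. The ±25% material scenario and the Monte Carlo material
multiplier touch exactly these named items and nothing else.

The recycle route is deliberately **not** calibrated. It is costed with the
unchanged ATPS configuration: the named ATPS chemical lines are charged at
their steady-state fresh-demand fractions (40%/80%/80%) and the filter count
is recomputed from the diluted back-extraction output (250 L vs 120 L, i.e.
5 filters vs 3). The resulting $5,421.95/g — a ~$30 saving, within 0.15% of
the published $5,430 — therefore emerges from the mass balance, which is the
pipeline's main non-circular check: material savings of $2,440/batch are
almost cancelled by $2,200/batch of extra filtration, reproducing the
finding that recycling barely moves the CoG/g because the UF/DF burden
grows.

## ATPS volumes and the back-extraction balance

The first system is 12x the sample volume (inside the reported 10–20x range
for ATPS operation volumes), with 40% of it forming the product-rich top
phase; the stream continuing downstream is that top phase (4.8x the sample,
120 L), since the bottom phase is discarded. The second system is sized at
`10 / 0.56` times the sample so that the two reported outputs hold
simultaneously: the collected bottom phase is 56% of the second system and
exactly 10x the original sample input.

Component flows use density 1 kg/L and fixed split fractions. Per-batch
inventories (PEG 45 kg, first-system ammonium sulfate 40 kg + 20.7 kg fresh
in the second system, NaCl 24 kg at 25 L sample scale) and top-phase split
fractions are chosen so the composite recycle fractions come out at exactly
60/20/20 and the second system is salt-dominated (7.8% ammonium sulfate vs
6.6% PEG w/w) with the larger bottom phase — the two stated feasibility
conditions for back-extraction, both enforced as preconditions. Mass
conservation (fresh + recycled in = discarded + collected + recycled out)
holds exactly by construction and is tested. Product partition is
all-or-nothing to the destination phase scaled by the step recovery; the
back-extraction step carries yield 1.0, keeping the recycle route's
composite DSP yield at 66% (no product loss for the second stage is
reported, and the recycle route's published economics are nearly identical
to plain ATPS).

Exact concentrations of the uricase ATPS are not modelled; charges and
splits are exposed as free configuration parameters.

## Sensitivity analysis

One variable at a time takes its best/base/worst value with everything else
at base: titer 0.577/0.484/0.392 g/L; DSP yield +10/0/−10 percentage points
(additive on the composite yield); material cost ×0.75/1.00/1.25 on the
named items; labor location Mexico/UK/USA with the printed wage tables
(carried verbatim, although the nominal "best" location's wages are not
uniformly lowest — spans are absolute, so rankings are unaffected). The
tornado span is `|CoG(worst) − CoG(best)|` in dollars, ranked descending
with alphabetical tie-break. The headline orderings (yield first for
chromatography, titer first for ATPS, materials above labor for ATPS) are
emergent consequences of the relative parameter ranges — ±10 points is
±23% of a 43.2% yield but only ±15% of 66% — not assertions wired into the
fixture.

## Monte Carlo and convergence

Titer ~ Triangular(0.392, 0.484, 0.577) and yield delta ~ Triangular(−10,
0, +10), drawn independently by an explicit inverse-CDF transform of
seeded numpy PCG64 uniforms (algorithm written out so the reproducibility
guarantee is part of the contract, cross-checked distributionally against
numpy's own triangular sampler). Draws that push the yield outside (0, 1]
are rejected, logged and resampled. The cumulative moving average of CoG/g
is tracked; the run is declared converged at the first index where it moves
less than 0.5% (relative) over a trailing 50-run window. The window/tol
rule is this package's own (only "stable after a few hundred runs" is
reported externally); convergence is reported, never imposed, and sampling
continues to `n_max` (default 1000). With the packaged configuration
convergence typically occurs between runs 50 and 150.

## Surrogates and overlap

`fit_linear` fits `cog ~ titer + dsp_yield_delta` by OLS (statsmodels) with
two-sided t-tests; significance is asserted at α = 0.01. Published
case-study coefficient triples are packaged verbatim as metadata, but all
quantitative work uses the *recentred* form
`cog = base + βT (titer − 0.484) + βY Δ`, anchored at each route's printed
base CoG/g — the raw published intercepts are dimensionally inconsistent
with those base values under any obvious unit convention, so the variable
scaling behind them is unrecoverable and only the slopes and base points
are treated as testable content.

The overlap analysis evaluates both recentred surrogates over the parameter
supports. The overlap interval runs from the minimum possible
chromatography CoG/g to the maximum possible ATPS CoG/g. The headline
fractions are the share of each process's full possible value range
occupied by that interval: 24.95% for chromatography ("must operate in
roughly the top quarter of its possible costs") and 54.48% for ATPS. This
operationalization was chosen after directly testing the alternative —
the fraction of sampled draws falling inside the interval — which yields
~3%/~43% and cannot reproduce the published 23%/52% pair; the range-based
reading reproduces both to within ~2.5 points simultaneously. Draw-
membership fractions are still computed and reported as diagnostics, and
the residual discrepancy is documented rather than tuned away.

## Synthetic data

`synthetic_mc_surface` generates noisy planes with known coefficients over
the packaged triangular supports, used to validate the fitter independently
of the cost engine (exact recovery at zero noise; RMSE shrinking ~1/√n
under noise). It emulates only the linear-response structure the surrogate
analysis assumes; it does not emulate the mild convexity of the true
engine response (CoG/g is affine in `1/(titer × yield)`), so passing
recovery tests says nothing about linear-model adequacy on real cost data.

## Numerical choices and problem sizes

Fractional batches keep the response smooth; per-step fixture yields are
stored at full float precision so composites equal 0.432/0.66 to ~1e-15;
calibration is exact arithmetic (no iterative solver); filter counts use a
ceiling rule, the one non-smooth element retained because filter lifetime
is genuinely discrete. Default problem sizes: 1000 Monte Carlo runs per
flowsheet, 400–500 runs for surrogate fits in tests, 100,000 paired draws
for overlap diagnostics — all chosen so the full pipeline completes in a
few seconds on one CPU while keeping Monte Carlo standard errors well
inside the tolerances tested.

## Known limitations

* The per-category cost splits and named material line magnitudes are
  calibration choices, not supplier data; only the anchored totals, the
  labor share and the qualitative orderings are externally validated.
* Stream volumes through centrifugation and homogenization are held at
  1.0x; only ATPS, back-extraction and UF/DF move volume materially.
* The recycle saving depends on the net of material credits and filter
  growth; with different filter pricing the sign of the ~0.5% difference
  could flip, which is consistent with the published finding of "no clear
  difference" between the two ATPS routes.
* No correlated-parameter sampling, no variance reduction, no interaction
  or higher-order surrogate terms.
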