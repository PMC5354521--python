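# Methods

`cellenergetics` prices cellular structures in a single currency — ATP
hydrolyses — and compares those prices with how much ATP a cell of a given
size has to spend. This note documents the models, their assumptions, the
defaults, and what the synthetic data generator does and does not emulate.

## Energy budgets

A cell's lifetime energy use is split into maintenance and growth:

* maintenance rate `C_M = 0.39e9 · V^0.88` ATP/cell/hour,
* growth cost `C_G = 27e9 · V^0.97` ATP/cell,
* lifetime budget of one division `C_T = C_G + t·C_M`, with `t` the
  division time in hours and `V` the cell volume in μm³.

The coefficients are empirical cross-species constants, already normalized
to 20 °C; no temperature correction is applied by this package. The
exponent standard errors attached to these laws elsewhere in the package
(0.07 and 0.04) mean neither law is distinguishable from isometry. Budgets
are stored as raw ATP counts, not units of 1e9, so that composition of
quantities can never silently mix scales; the reporting layer divides for
display.

## Lipid and membrane costs

Glycerophospholipid costs are affine in mean fatty-acid chain length `N_L`
and mean unsaturated carbons per chain `N_U`:

| cost | bacteria | eukaryote |
|---|---|---|
| total (evolutionary) | `320 + 38(N_L−16) + 6N_U` | `340 + 40(N_L−16) + 6N_U` |
| reduced (direct ATP) | `110 + 7(N_L−16) + 6N_U` | `120 + 9(N_L−16) + 6N_U` |

The total cost includes the ATP-generating potential of diverted
precursors; the reduced cost is the direct ATP spend only. The formulas
are accepted for `N_L ≥ 10`; shorter chains emit an `ExtrapolationWarning`
and chains short enough to drive the cost non-positive raise a
domain-of-validity error. Cardiolipin has four acyl chains and is not
representable by the two-chain model, so it ships as a predefined species
with explicit overrides (total 640, reduced 240 ATP/molecule); the package
deliberately does not attempt to re-derive those numbers from the formula.
Average per-lipid costs used as named constants: direct cost 123
ATP (bacterial plasma membranes), 143 (eukaryotes, whole-cell and plasma),
155 (mitochondrial membranes), and a mean *total* mitochondrial lipid cost
of 440 ATP. Membrane-composition means are mole-fraction weighted; whether
the published averages were mole- or mass-weighted is not stated in the
source literature, and mole-fraction weighting is the natural choice for
per-molecule costs.

A bilayer of area `A` μm² contains `2/a_h` lipids per μm², with head-group
area `a_h = 6.5e-7` μm² by default (observed head groups sit within ~10% of
this), giving the familiar coefficient `C_L ≈ 3.1e6 · c̄_L · A`. An
optional `protein_area_fraction` (0–0.5) discounts the lipid count for
membrane area occupied by protein; the default 0 matches the headline
numbers, and because proteins never exceed half a membrane the correction
is at most a factor of 2.

The relative cost of mitochondrial membranes composes the total
mitochondrial area law `A = 3.0·V^0.99` (inner + outer, all mitochondria)
with `c̄_L = 440` and the growth law, giving `s_c ≈ 0.15·V^0.02` — about
15% of the growth budget of a 1 μm³ cell, nearly independent of size. The
explicit composition is ground truth; the `0.15·V^0.02` shortcut is
provided as a labelled approximation (0.15 is a rounding of
3.0769e6×440×3/27e9 = 0.1504, and the two agree to <1% over
V ∈ [0.2, 1e4]). Composing the SEs of the area exponent (0.08) and growth
exponent (0.04) in quadrature gives 0.089 for the exponent of `s_c`; the
published SE for that exponent is 0.08, so the propagation rule used there
was evidently not plain quadrature — this package reports quadrature and
documents the discrepancy rather than matching the printed value.

A trait's relative cost acts as a selection coefficient `s_c` against it;
the net advantage `s_n = s_a − s_c` is visible to selection only when
`|s_n|` exceeds the drift threshold `1/N_e` (haploid) or `1/(2N_e)`
(diploid). Maintenance costs of mitochondrial lipids are not modelled
(unknown in the source data).

## Membrane geometry and apportionment

Closed forms cover spheres, spherocylinders (`SA = 2πrL + 4πr²`,
`V = πr²L + (4/3)πr³`), and triaxial ellipsoids (exact Legendre incomplete
elliptic integral form, with spheroid/sphere degeneracies special-cased);
tests verify them against numeric surface integration to 1e-6 relative.

Total mitochondrial membrane area is extrapolated from outer-membrane
measurements as `outer × (1 + inner:outer)`, with the cristae-inclusive
inner:outer ratio defaulting to 4.6 — the stated cross-species average —
even though the four individually published ratios (5.0, 2.4, 2.5, 5.2)
average 3.775; the latter is exposed via
`mean_observed_inner_outer_ratio()` for sensitivity analyses.

`membrane_budget_table` apportions the lipid cost of a per-compartment
membrane inventory (plasma, mitochondria, nucleus, ER+Golgi,
vesicles/vacuoles; plastids excluded by convention) across compartments,
normalizes shares to sum to one, and reports the total membrane fraction of
the growth budget plus the internal (non-plasma) share. When a single
generic per-lipid cost is used (default: the eukaryotic mean reduced cost,
143 ATP) the report is flagged as a generic-cost approximation — the
published per-species apportionments used species-specific compositions,
and the generic recomputation does not reproduce them exactly (e.g. the
picoalgal total fraction computes to ≈0.25 against a published 0.324).
The published four-species apportionment table is shipped verbatim as
`table1()`, and `apportionment_from_shares` does the internal-membrane
arithmetic on published numbers. Its row products are reported as
computed; the one published "~18% of total budget" figure for the picoalga
that conflicts with 0.324×0.444 ≈ 14.4% is surfaced but never asserted.

## Packing and turnover

Subunit copy numbers divided by per-complex stoichiometry give independent
estimates of assembled complexes per cell; the summary is their arithmetic
mean, with min (the conservative assembled limit — the scarcest subunit
caps complete complexes) and max also reported. Occupancy is the pure area
ratio `n × footprint / area` (footprints: bacterial F0F1 64 nm²,
eukaryotic 110 nm², ETC unit 570 nm²); no steric packing model is imposed
because optimal packing is genuinely unclear, but fractions above 1 warn.
Note the reference E. coli numbers (3018 complexes, 64 nm², 15.8 μm²)
yield 1.22%, not the 1.8% sometimes quoted alongside them; this package
reports the arithmetic as-is. The ETC argument uses the factor 5 where the
source argument uses it: mean bacterial synthase occupancy 1.1% × 5 = 5.5%.

Required turnover divides the ATP share of the lifetime budget by
(division time × complex count): `budget × share / (t × 3600 × n)` ATP/s
per complex. The default `atp_share = 0.15` encodes that only ~15% of
biosynthetic energy flows through ATP hydrolysis (the rest through
NADH/NADPH oxidations at ~3 ATP equivalents each: 1/(1+1.5×3) ≈ 18% for
amino acids, 1/(1+2×3) ≈ 14% for lipids). Measured maximal synthase rates
(195/s bacterial mean, 120/s yeast, 440/s bovine heart) are shipped as
comparison constants only.

## Synthetic data generator

The generator emulates cross-species trait compilations as power laws in
cell volume with multiplicative lognormal noise — exactly the model the
log-log OLS fitter assumes. Volumes are sampled log-uniformly (real
compilations span ~4 orders of magnitude); defaults are 0.03–10 μm³ for
bacteria and 0.2–2000 μm³ for eukaryotes, bracketing the smallest and
largest cells the reference analyses discuss. Generating relations default
to the published fits where one exists (mitochondrial area `3.0·V^0.99`,
ribosomes `7586·V^0.82`, ATP synthase `113·S^1.26` against *surface area*,
division-time exponents −0.17 bacteria / +0.13 eukaryotes); the published
record gives only the division-time exponents, so the coefficients are set
once to representative round values (1 h and 3 h at V = 1 μm³). Default
scatter is `sd_log10 = 0.2` (≈ a factor 1.6 either way), typical of such
compilations. Seeds are mandatory and never defaulted.

What the generator does *not* emulate: phylogenetic correlation between
pseudo-species, heteroscedastic or asymmetric scatter, measurement error
in `x`, and group discontinuities. Passing recovery tests therefore show
that the estimator is correct and calibrated under its own model (±2 SE
intervals empirically cover the truth ~95% of the time at n = 50,
sd = 0.2), not that real cross-species data satisfy that model.

## Fitting and numerical choices

`fit_power_law` is unweighted OLS of log10(y) on log10(x); the coefficient
is `10^intercept` and both SEs are the usual OLS ones on the log10 scale
(base 10 chosen so the intercept SE is comparable with published log-scale
values; the exponent is base-invariant). Non-positive data are rejected
with the offending records named, never offset — silent pseudo-counts
would corrupt exponents. With noiseless input the residual variance
underflows; SEs are then reported as exactly 0 and r² as 1. Exponents of
products/ratios of power-law quantities add/subtract, with composite SEs
combined in quadrature under an assumed independence of the two fits; the
one published composite (SE 0.12 from 0.04 and 0.11) validates the rule.
A common-slope, per-group-intercept fit is provided as a convenience for
inspecting prokaryote/eukaryote continuity; no test statistic accompanies
it.

Problem sizes in the test suite (≤ 200 replicate fits of n = 50; 25
replicates of n = 100 for the ribosome-scaling stand-in) are chosen so the
whole suite completes in seconds while leaving the Monte Carlo bands
(85–99% coverage, ≥ 90/100 recovery) far from their thresholds.

## Reproducibility

`run_pipeline` writes every constant and seed it used to `run_log.txt`,
and its numeric reports are byte-identical across reruns with the same
config. Reports carry full-precision values plus an `as_printed` rendering
at 2–3 significant figures mirroring the "~" style of the literature;
rounding happens only in that layer.
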