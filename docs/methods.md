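# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the known limitations.  No empirical claim here goes beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## FIF molecular-brightness analysis

**Model.** For immobile shot-noise-limited photon counting, pixel counts in
a membrane region are Poisson and `ε = σ²/⟨I⟩ − 1 = 0`.  Clustered
fluorophores add super-Poisson variance: for oligomers of size k placed
randomly with per-pixel rate μ and `c` counts per fluorophore (zero
background), `⟨I⟩ = ckμ` and `σ² = ckμ + (ck)²μ`, so `ε = ck` — brightness
is proportional to oligomer size, which is the entire inferential basis of
the method.

**Choices.**

- *Log base*: brightness distributions are treated as log-normal and
  histogrammed as `log₁₀ ε`.  Base 10 keeps the brightness scale consistent
  with the log₁₀ convention of the bias coefficients.  (Natural log would
  only rescale `m`, `s` and `Z` consistently; the Z-test is base-invariant.)
- *Non-positive brightness*: `ε ≤ 0` has no logarithm.  Such regions
  (possible by sampling noise in dim regions) are discarded before
  histogramming and the discarded fraction is reported on the fit, rather
  than shifting all values, which would distort the log-normal shape.
- *Binning*: Freedman–Diaconis on the log values by default, overridable.
- *Histogram fit weighting*: the Gaussian is fitted to max-1-normalized bin
  counts.  Plain unweighted least squares makes `se_m` mis-calibrated
  (measured ≈86–91% coverage of `|m−m_true| ≤ 2·se_m` on log-normal
  samples); weighting each bin by its Poisson counting error
  `√count/max_count` (absolute sigma) restores ≈95% coverage, so Poisson
  weighting is the default and `weights="none"` gives the plain variant.
  The location/width estimates are essentially identical either way.
- *ROI tiling*: non-overlapping from the top-left origin, partial border
  tiles dropped; with a mask, only tiles fully inside the mask are used.
- *`n_cells` is metadata*: the comparison error `q = s/√n_cells` divides by
  the number of cells analyzed, not the number of ROIs — ROIs within a cell
  are not independent.  This makes the Z-test conservative when many ROIs
  per cell are available: the false-positive rate on same-population
  comparisons is far below the nominal 5%.
- *Density*: receptors/μm² = (mean intensity − background)/(counts per
  fluorophore × pixel area); background defaults to none and the
  calibration constant is an input.

## Dose-response scaling and Hill fitting

**Scaling chain.** Each gel has an unknown multiplicative factor.  The
protocol: per-gel max → 1; average across ≥3 gels on a common concentration
grid (grids differing by ≤1% relative are merged; otherwise an error);
re-normalize the mean curve's max to 1, scaling the SEMs by the same
factor; finally multiply each ligand's curve by its gluing-gel coefficient
(ligand lane average ÷ highest ligand lane average).  The chain preserves
within-gel intensity ratios, and exactly one ligand (the full agonist)
keeps maximum 1.

Note an identifiability consequence used by the recovery benchmarks: for a
*single-ligand* experiment, max-normalization removes the absolute efficacy
— the noiseless chain converges to `EC50` unchanged but plateau
`1 + EC50/x_max` (x_max the top dose), and only the glue step restores
relative efficacies across ligands.  Recovery tests therefore assert
against that normalized truth.

**Loss curves.** Abundance readouts (receptor level, collagen) decrease
with dose; per gel the zero-dose baseline is set to 1 and
`loss = 1 − scaled value`, giving an increasing curve through the origin.
Loss curves are averaged without max-renormalization.

**Truncation.** Curves are cut at the largest dose whose mean response is
≥ 0.9 × the curve maximum ("within 10%", read as relative, consistent with
the 5–10% blot error scale); all smaller doses are kept.  This is the only
accommodation of biphasic (bell-shaped) curves: the declining limb is
excluded, no biphasic model is fitted.

**Fit.** `y = x·E_top/(x + EC50)` by Levenberg–Marquardt
(`scipy.optimize.curve_fit`, up to 100 000 evaluations), starting from
`E_top⁰ = max(y)` and `EC50⁰ =` the dose nearest half-max.  Zero-dose
points participate with model value 0.  The optimizer is unbounded (LM does
not support bounds); non-positive estimates and non-convergence are flagged
on the result instead.

**Weighting (a deliberate deviation).**  Weights are the inverse square of
the per-point error, but the *error model* matters.  With only ~3 gels the
per-point SEMs are estimated from 3 numbers and are extremely noisy;
literal `1/sem²` weights measurably degrade the fit (EC50 estimator sd
inflated ~35%) and destroy interval calibration (≈74% coverage of ±2 SE
instead of 95%).  Since blot noise is proportional to signal, the default
`error_model="pooled_relative"` pools the relative error
`√mean((semᵢ/yᵢ)²)` over the curve and uses `σᵢ = rel·yᵢ` as absolute
sigma; measured coverage is ≈95% for both parameters, matching the
known-sigma ceiling (~94%).  `error_model="per_point"` provides the literal
scheme (zero/missing SEMs replaced by the curve's median positive SEM, SEs
scaled by reduced chi-square) for comparison; the property "all-equal SEMs
≡ unweighted fit" holds for that model by construction.

## Bias coefficients

`β′ = log₁₀[(E_top/EC50)_num · (EC50/E_top)_den]` per ligand;
`β = β′(ligand) − β′(reference)`.  Properties relied on (and tested):
invariance to common per-response rescaling of E_top (unit cancellation —
the reason β is comparable across readouts), antisymmetry under swapping
the response pair, and transitivity in the reference
(`β(L₁ vs L₂) = β′₁ − β′₂`).

- *Log base 10*: the published coefficient magnitudes are reproduced only
  in base 10.
- *Response ordering is explicit.*  The API takes numerator/denominator
  arguments and never infers order from labels; the bundled bias map pins
  numerator = second-listed response for the phosphorylation/downregulation
  pairs and numerator = first-listed for the collagen-loss/growth-arrest
  pair, which reproduces the published magnitudes with a single convention
  per row.  Computed from the reference fit table with one fixed global
  ordering, the two row families have opposite signs relative to their
  labels; the magnitudes are unambiguous.
- *Error propagation*: four variants — `functional` (one-sided positive
  perturbation, `SE = √Σ[f(x+δxᵢeᵢ)−f(x)]²`), `functional_symmetric`
  (symmetric difference), `derivative` (central-difference first-order),
  and `montecarlo` (seeded normal draws; undefined draws dropped).  For
  log-ratios at small relative errors all four agree; at large relative
  errors (≳30%) the one-sided functional variant undershoots and the
  symmetric variant tracks Monte Carlo within ~10%.  β's SE combines all
  eight parameter errors in one propagation, not by adding the two β′ SEs
  in quadrature.
- *ANOVA from summary statistics*: `SS_between = Σnᵢ(meanᵢ−grand)²`,
  `SS_within = Σ(nᵢ−1)·nᵢ·semᵢ²`, `F = MS_between/MS_within` with
  `(k−1, Σnᵢ−k)` degrees of freedom — exactly the raw-data one-way ANOVA,
  no Welch correction.  Typical inputs are the per-ligand β′ values with
  n = the number of fitted points.
- *Slope comparison*: two OLS fits, residual variance pooled over both
  series (df = n₁+n₂−4), two-sided t on the slope difference — equivalent
  to the interaction-term t-test of a joint regression with separate
  intercepts (verified against statsmodels).

## QI-FRET

`x_A = acceptor/(donor+acceptor)`, `Ẽ = E/x_A` — valid only in the
constitutive-dimer regime, which is checked by regressing E on total
concentration (`constitutive` iff the slope is not significant at 0.05; at
least 20 vesicles spanning ≥3-fold concentration).

- *`x_A` cutoff 0.1*: dividing E by a small acceptor fraction amplifies
  measurement noise without bound; excluded vesicles are counted and the
  reason recorded.
- Per-vesicle Ẽ outside [0, 1.2] is kept for the histogram (it is honest
  noise) but a mean outside (0, 1) has no distance.
- Distance: `d = R₀((1−Ẽ)/Ẽ)^{1/6}` under the free-rotation assumption;
  `R₀ = 53.1 Å` (eYFP/mCherry) by default and overridable.  The distance SE
  is propagated from the Gaussian mean's SE by the functional approach.
- **Known discrepancy**: published distances of 55/56/60 ± 1 Å are not
  reproducible from the published intrinsic-FRET values 0.54/0.52/0.42 with
  `R₀ = 53.1 Å` (0.42 gives 56.0 Å, not 60 Å; the printed trio implies an
  effective `R₀ ≈ 57 Å`).  The package computes the self-consistent value
  from whatever `R₀` it is given and does not attempt to match the printed
  distances.

## Synthetic generators

All generators are pure functions of (spec, seed) with no global state.

- *FIF images*: oligomers of sampled size placed uniformly at random, each
  contributing `k·c` to one pixel's Poisson rate, plus uniform background.
  Defaults: 150 receptors/μm² (inside the measured 100–200 range),
  70 nm pixels, 5 counts/fluorophore, zero background.  Not emulated: PSF
  blur, membrane topology/ruffles, detector afterpulsing, cell-to-cell
  expression variability.  A green discrimination test therefore shows the
  statistic separates ideal monomer/dimer fields — not that it survives
  optical artifacts.
- *Band tables*: `intensity = gel_scale · Hill(x) · (1+N(0, 0.07))`,
  clipped at 0; gel scales log-normal (σ = 0.3 log-units); noise default 7%
  (the middle of the stated 5–10% blot error).  The biphasic option
  multiplies doses above a threshold by `(threshold/x)^p` — a
  phenomenological shape for exercising truncation, not a mechanism.
  Gluing gels re-run each ligand's top-dose sample (3 lanes) under one
  shared hidden scale.
- *Vesicles*: donor/acceptor log-uniform over a 40-fold range,
  `E = Ẽ·x_A + N(0, 0.05)`.  Defaults match the benchmark condition
  (300 vesicles, Ẽ = 0.42).  Not emulated: spectral bleed-through,
  per-vesicle calibration error (which would correlate E with x_A).

## Degenerate inputs and numerical conventions

- Histogram fits need ≥3 non-empty bins and (for brightness) ≥50 positive
  values; failures raise; optimizer non-convergence flags the result.
- All-zero gels, missing zero-dose baselines, ligands absent from the glue
  table, non-positive Hill parameters entering β, both-zero vesicle
  concentrations: explicit errors.
- Single-gel curves warn and carry NaN SEMs (the fit then runs unweighted).
- Truncation keeps a non-empty prefix by construction (the argmax always
  qualifies).
- Monte Carlo propagation errors out if more than half the draws are
  undefined.

## Limitations

- Brightness → absolute oligomer size is only proportional; no attempt is
  made to calibrate k beyond the monomer/dimer ratio property.
- The bias analysis assumes the two responses are measured in the same
  cellular background per pair; it cannot detect system bias from
  differential receptor expression.
- The ANOVA-from-summary and the ±2 SE recovery criteria assume
  approximately normal parameter estimates; EC50 estimates are mildly
  right-skewed at 3-gel noise, which is the main reason coverage sits at
  ~94–96% rather than exactly 95%.
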