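# Methods

## Single-encounter chain model

The kinetic core is a linear chain of irreversible first-order
transfers `S0 → S1 → … → S_{n−1} → S≥n`. The model assumes:

- *single-encounter conditions*: excess unlabelled competitor prevents
  rebinding, so a molecule that dissociates never advances further;
- each transfer is pseudo-first-order with a constant observed rate
  `k_i` (per second) — E2~ubiquitin recharging, NEDD8 cycling and
  substrate rebinding are deliberately outside the model;
- species beyond the `n`-th resolvable gel band are pooled into one
  absorbing aggregate `S≥n`, matching how long chains merge into a
  smear (published rate tables stop at the third transfer for the same
  reason).

Units are seconds and nanomolar throughout the library; conversions
happen only at I/O boundaries.

An optional per-state dissociation rate `d` (default 0) models release
from the ligase: the observed `S_i` is then bound + released material.
The default of 0 reflects that tabulated single-encounter kobs values
are *observed* rates which already fold in any release. Both variants
are provided because the closed-form family admits either reading.

### Numerical evaluation

For pairwise-distinct rates the solution is the Bateman sum of
exponentials. That formula cancels catastrophically as rates approach
each other, so the implementation evaluates the equivalent quantity

    S_i(t) = (k_1 … k_i) · (−1)^i · f[λ_0, …, λ_i],   f(λ) = e^{−λt}

where `f[…]` is a divided difference over the decay rates. The
Hermite (confluent) table runs in extended precision; any node cluster
with spread `Δλ·t < 1e−6` is evaluated as the k-th derivative at the
cluster mean. The threshold is the ε^(1/3) crossover between the
confluent approximation error O((Δλ·t)²) and the quotient cancellation
error O(ε/(Δλ·t)), so exact ties, adjacent-float near-ties and
well-separated rates are all accurate: the worst deviation from a
tight adaptive ODE reference over 1000 random rate sets (including
planted near-degeneracies down to relative spacing 1e−15) is ~2e−9.
A matrix exponential of the bidiagonal generator was evaluated as an
alternative for the degenerate case and rejected: on near-defective
generators it only reached ~5e−8 absolute. The matrix-exponential path
is retained solely for the dissociation-augmented state space, where
accuracy demands are milder.

The per-molecule simulator draws independent exponential waiting times
per step (with a release/advance competition when `d > 0`) and is used
to cross-validate the closed form; it is seed-reproducible.

## Rate estimation from quench-flow densitometry

Each gel lane is normalised to fractions of total lane signal; the
estimator minimises squared residuals between observed and model
fractions over all time points, replicates pooled into one objective.

Key choices:

- **Tracked species only.** Lane fractions sum to one, so the terminal
  aggregate column is a deterministic linear combination of the
  tracked columns. Fitting `S0 … S_{n−1}` uses all the information;
  additionally including the aggregate would deflate the
  Gauss–Newton covariance by ≈ √(n/(n+1)) and mis-calibrate the
  standard errors.
- **Log-rate parameterisation with multi-start.** Published transfer
  rates span 0.08–40 s⁻¹; optimising `log k` enforces positivity, and
  a log-spaced start grid over 10⁻³–10² s⁻¹ (plus staggered
  decreasing/increasing profiles) escapes local minima. Non-converged
  fits warn and are flagged on the result, never silent.
- **Unweighted least squares** by default (densitometry noise is
  approximately homoscedastic on the fraction scale); inverse-variance
  weighting from replicate spread is available.
- **Uncertainties.** Standard errors come from the Gauss–Newton
  covariance `s²(JᵀJ)⁻¹` with J evaluated in rate space at the
  optimum. A lane-clustered sandwich estimator was tested and was
  *worse* calibrated (too few clusters), so it was not adopted.
  Because the ± spread of published rate tables could be either fit
  SEs or replicate ranges, results expose both (`bse` and
  `replicate_ranges()`).
- **Goodness of fit.** χ² on residuals standardised by the pooled
  replicate noise SD, df = n_points − n_rates, stated in the result
  metadata. Without replicates the p-value is NaN.
- **Identifiability guards.** More rates than tracked-species columns,
  or fewer than two distinct time points per rate, raise an error
  rather than returning an unconstrained fit.

A genuine limit worth knowing: when an elongation step is much faster
than initiation (k₂/k₁ ≳ 100, as for the fastest published elongating
E2), the intermediate never exceeds k₁/k₂ of lane signal. At realistic
densitometry noise that step is information-limited — the estimator is
exact on noise-free data but no estimator can recover the step to
within ~10% at 2% band noise. The recovery tests document this
honestly rather than hiding it.

## Multi-turnover Michaelis–Menten stage

Velocity per point is `fraction_converted × [substrate]/([SCF] × t)`
(per minute); points above 20% conversion violate the initial-rate
assumption and carry a warning flag. The titrated E2/E3 plays the role
of `[S]` in `v = kcat·[E]/(Km+[E])`, fitted by
`scipy.optimize.curve_fit` with positivity bounds, initialised at
`Km = median concentration`, `kcat = 1.2 × max velocity`. R² is
computed against the mean model (the convention of common fitting
software). A fitted Km outside the titrated range warns that the
estimate is extrapolated. Efficiencies `kobs/Km` convert nM → M
(×10⁻⁹) and are reported both raw and rounded to 2 significant
figures, matching how such comparisons are typically printed; fold
ratios keep the unrounded quotient alongside the integer fold.

## SRM quantification

`copies/cell = ratio × spike(fmol) × 10⁻¹⁵ × N_A / n_cells`;
concentration uses a *spherical* cell volume from the counter's mean
diameter — the true volume model of the original source data is not
recoverable, so the sphere assumption is declared in the result
metadata. Ratio orientation is fixed as endogenous(heavy) over
spiked(light). A default enrichment multiplier of 2 converts whole-
cell concentration to the assay concentration, reflecting reported
modest nuclear enrichment of the elongating E2; it is configurable.
Isoform pools (e.g. UBE2D1/2/3/4 share spike peptides) are treated as
one species. Replicates sharing a protein label are averaged with an
SEM.

## Screen differentials and off-target scan

Differential score = experimental − mean(controls), computed only on
genes shared by every table; unshared genes are dropped and reported,
never imputed. Gene matching is by exact identifier. The off-target
scan is a Hamming-distance filter over a *provided* candidate-site
list; genome-wide enumeration (PAM search over annotation) is out of
scope. No p-values are attached to differentials: the null model used
in the original screen analysis is not specified, and inventing one
would overstate certainty.

## Synthetic-data generators

Each generator inverts its analysis stage, so at zero noise the
round trip is exact — this anchors the self-consistency tests.

- **Quench-flow**: closed-form fractions → band intensities (scale
  10⁴) → additive Gaussian noise (SD expressed on the fraction scale),
  negatives clipped to zero → per-lane renormalisation. Noise lives on
  bands because densitometry noise is a signal-level phenomenon;
  renormalisation then induces the mild anticorrelation between
  species fractions seen in real lanes (property-tested). The default
  grid is 13 log-spaced points over 0.01–10 s, the span of a
  quench-flow instrument up to the conventional 10 s end point;
  duplicates by default. The clip at zero introduces a small upward
  bias in near-zero fractions and hence ~1% bias in the fastest rate —
  visible as slightly sub-nominal (≈ 0.84 per-rate) 2·SE coverage for
  initiation rates while pooled coverage stays ≥ 0.9.
- **Titrations**: 2-fold dilution series from a top concentration,
  true MM velocities inverted to conversions, multiplicative CV noise,
  re-derived through the velocity formula so the 20% rule applies to
  synthetic data too.
- **SRM**: true concentration → implied heavy:light ratio →
  multiplicative CV noise.
- **Screens**: control tables Normal(0, sd) per gene, planted effects
  added to the experimental table.

The true magnitude of densitometry noise is not published; the default
σ = 0.02 (fraction scale) is of the order seen in duplicate gel
quantification and makes recovery experiments meaningful. It is a
`NoiseSpec` parameter, not a constant.

What the generators deliberately do **not** emulate: correlated
lane-to-lane drift, gel smearing between adjacent bands, saturation of
the phosphor signal, SRM transition-level interference, or
guide-efficiency variation in screens. Passing recovery tests
therefore demonstrate estimator correctness under the stated noise
model, not robustness to every real-world artefact.

## Problem sizes

The acceptance computations use 1000 random rate sets for the
ODE-equivalence check, 10⁴ molecules × 25 seeds for simulator
consistency, 50 seeds per rate-set fixture for quench-flow recovery,
50–100 seeds per titration fixture, 100 seeds for SRM and screen
recovery, and 1000-gene score tables — sizes at which the Monte-Carlo
error of each reported statistic is comfortably below the margin it is
judged against.

## Known limitations

- The chain model tracks at most as many rates as resolvable species;
  it cannot apportion flux between dissociation and transfer from
  observed fractions alone (both variants fit equally well at `d`
  small).
- Gauss–Newton SEs understate uncertainty when a rate is weakly
  identified (flat likelihood directions); the multi-start history is
  not used to detect multimodality.
- The SRM stage accepts one pre-rolled ratio per protein/replicate;
  peptide-level roll-up happens upstream.
- `GeneScoreTable` holds scores in memory; screens beyond ~10⁶ genes
  would need a chunked path (not a realistic constraint for gene-level
  tables).
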