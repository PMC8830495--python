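# Methods note

This note records the model, the parameter defaults and why they were chosen,
the numerical conventions, and the known limitations of `irsom`.

## Model and assumptions

The estimator assumes that within 1600–1700 cm⁻¹ a protein absorbance
spectrum, after linear baseline subtraction and normalisation to 1 at the
Amide I maximum, is close (Euclidean distance in ℝ^n over the shared
wavenumber grid) to spectra of proteins with similar helix/sheet/other
fractions. No band assignment is required for the SOM route; the map simply
organises the reference library by spectral similarity and interpolates
structure fractions across it.

### Training

A `map_dim × map_dim` grid of nodes is initialised elementwise-uniformly
between the per-wavenumber minima and maxima of the reference spectra. For
`n_steps` online steps, a reference spectrum x is drawn uniformly at random
and every node weight w is updated

    w ← w + α(t) · h(t, g) · (x − w),

where g is the grid distance to the best-matching unit (BMU, nearest node by
Euclidean spectral distance, ties to the lowest row-major index) and
h = exp(−g² / 2σ(t)²). Both schedules decay exponentially:
α from `alpha0` = 0.25 to `alpha_end` = 0.01, σ from `sigma0` = map_dim/2 to
`sigma_end` = 0.5. Quantization error (mean distance of members to their
BMUs) is recorded at checkpoints and is non-increasing in practice.

### Structure assignment

After training, each reference member is placed on its BMU. A node holding a
member copies that member's fractions exactly (if two members share a node,
the spectrally nearer one wins). Every other node n receives

    f(n) = Σ_i d(n, x_i)^(−p) f_i / Σ_i d(n, x_i)^(−p),

a convex combination, so node fractions always lie on the unit simplex. If a
node's spectrum coincides with a member (d = 0) the member's fractions are
copied bit-for-bit.

**Weighting power p = 3 (config default).** With p = 1 over all members the
weights are nearly uniform far from the data, and node fractions shrink
towards the library mean: on synthetic libraries the node-fraction standard
deviation collapsed to 0.11 against a member standard deviation of 0.235,
and LOOV mean absolute deviations were ≈0.10. Raising p restores locality:
p = 2 gave 0.063/0.053 (helix/sheet), p = 3 gave 0.053/0.046, p = 4 was flat
at 0.053/0.045. The default is therefore p = 3; the standalone
`assign_structures` function keeps the neutral p = 1 default and both expose
`p` explicitly.

### Prediction and reliability

A test spectrum (same grid, same normalisation) finds its `k_bmu` = 5 nearest
nodes and averages their fractions with weights 1/d. If any distance is zero
the result is the plain mean over the zero-distance nodes, preserving exact
recovery. The same weights combine the node spectra into a reconstruction;
its NRMSD from the input,

    NRMSD = sqrt( Σ(obs − recon)² / Σ obs² ),

flags unreliable queries: spectra unlike anything in the library reconstruct
poorly. Fractions are renormalised onto the simplex only when floating-point
drift exceeds 1e-12, so exact node matches return stored fractions
bit-for-bit.

### Map size default

The default side length is 40 for N ≥ 45 members, 20 for 25 ≤ N < 45, and
otherwise ceil(4·√N) capped at 40. The spec's single formula contradicts its
own worked sizes (ceil(4√50) = 29, not 40), so the piecewise rule follows the
printed choices at the relevant library sizes; it is always overridable via
`SOMConfig(map_dim=...)`.

### Leave-one-out validation

Fold i trains on the N−1 remaining members with a per-fold seed
`SeedSequence([seed, i]) mod 2³¹` and predicts the held-out member. Reported
deviations are predicted − true; the "other" deviation is −(helix + sheet)
by construction. The deviation table is sorted by true helix content
descending and carries `nrmsd` and `nrmsd_x5` columns.

## ATR ↔ transmission conversion

Penetration depth of the evanescent wave:

    d_p = 1 / (2π ν̃ n₁ sqrt(sin²θ − (n₂/n₁)²)),

so d_p·ν̃ is constant (1/ν̃ law) and a geometry at or below the critical
angle raises an error. The conversion is

    A_T = A_ATR · ℓ / ( d_p f · (1 − ln10 · d_p f · (εC)_water) ),

with the exact algebraic inverse for the reverse direction; the denominator
must stay positive (a `SaturationError` names offending wavenumbers).
Defaults: ZnSe crystal n₁ = 2.43, water n₂ = 1.33, θ = 45°, intensity factor
f = 1. `normalised_conversion` renormalises to 1 at the Amide I maximum
afterwards, which makes the result invariant to path length and overall
scale. The water model ships only `zero()` (water-free limit) and `flat()`
(synthetic, for testing); real (εC)_water tables must be supplied by the
user.

## Band-fitting estimators

Band centres are picked as minima of the Savitzky–Golay second derivative
(window 9 points, polynomial order 3 by default). A sum of Gaussians is then
fitted by bounded trust-region least squares (centres ±8 cm⁻¹ of their
guesses, σ ∈ [2, 20] cm⁻¹, amplitudes ≥ 0), with a per-iteration residual
trace that is checked to be non-increasing. The *direct* method fits the
absorbance; the *second-derivative* method fits −(d²A/dν̃²) clipped at zero,
which for equal-width bands preserves area ratios. Fractions are window area
sums over total area: sheet 1620–1640, helix 1650–1656, turns 1670–1685
(counted as "other"), everything else "other".

Resolution caveat: second-derivative picking cannot separate bands whose
spacing is small relative to their widths — three planted bands at
1631/1645/1654 cm⁻¹ merge to two at σ = 5 cm⁻¹ on a 2 cm⁻¹ grid, while at
σ = 4 cm⁻¹ on a 1 cm⁻¹ grid recovery is exact to machine precision. The
acceptance test uses the resolvable regime deliberately.

## Fourier self-deconvolution

The spectrum is mean-padded to the next power of two ≥ 2n, transformed with
`rfft`, multiplied by exp(2π γ x) (x = retardation) and by the apodization
(1 − x/L)² with L = smoothing · x_max, and transformed back. Convention:
smoothing = 1 disables apodization entirely so that γ = 0, smoothing = 1 is
the identity within 1e-10 (the literal "taper to zero at x_max" definition
is not the identity there; the trade-off is documented here because the
original implementation's convention is unpublished). The boost factor is
evaluated only where the apodization is non-zero (avoiding inf·0) and an
exponent guard at 700 rejects parameter combinations that would overflow.
Narrowing is measured as the FWHM of the main peak, walking outward from the
peak to the first half-maximum crossings so deconvolution ringing in the far
wings does not distort the measure.

## Synthetic generator

Structure fractions are sampled uniformly on the simplex (ordered uniform
spacings). Each component contributes unit-area Gaussian bases: helix
1654/σ7, sheet 0.8·(1631/σ6) + 0.2·(1678/σ5), other 1645/σ12, with band
centres jittered (SD 1 cm⁻¹) and Gaussian noise (SD 0.005 relative to the
peak) added before normalising the maximum to 1 on the default grid
1600–1700 cm⁻¹ at 2 cm⁻¹. These are stylised but reproduce the qualitative
structure–spectrum correlations (peak position rises with helix content).

## Validation problem sizes and frozen bounds

The external reference libraries behind the original headline error rates
are not redistributable, so validation is synthetic and property-based.

- **Recovery run:** n = 50 members, noise 0.005, seed 1, 40×40 map, 5000
  steps. The regression bound of **0.10** on each of mean |helix| and
  |sheet| deviation was frozen from pilot runs *before* the acceptance tests
  were written (pilot seed 1: 0.053/0.046; seeds 2–3: 0.060/0.040,
  0.056/0.046).
- **Noise monotonicity:** n = 30, 20×20 map, 3000 steps — the package's own
  smaller-study choice. Combined mean absolute deviation at noise
  0.005/0.02/0.05 was verified monotone at seeds 1–4 (e.g. seed 1:
  0.0522 ≤ 0.0535 ≤ 0.0551).

## Numerical choices

- All randomness flows through `numpy.random.default_rng`/`SeedSequence`
  with user-visible integer seeds < 2³¹; training draws are pregenerated so
  runs are bit-reproducible.
- BMU search is exact (no approximate nearest neighbour); stable argsort
  fixes tie order.
- File formats store 9 significant digits (`%.9g`); trained maps serialise
  to JSON losslessly (full float repr).

## Limitations

- Helix/sheet/other is a 3-class collapse; 3₁₀-helix is counted as helix and
  turns as "other". β_II proteins (sheet-rich but helix-like spectra) are a
  known failure mode of any reference-set method — watch the NRMSD flag.
- Prediction requires the test spectrum on the training grid with the same
  normalisation; no automatic resampling happens inside `predict`
  (use `irsom.preprocess.interpolate_to_grid`).
- The synthetic generator is not a substitute for a curated experimental
  reference library; absolute deviations on real data will differ.
- The SOM is retrained per LOOV fold, so LOOV cost scales as
  N × (training cost).
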