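# Methods

## Scope and model

The package implements a screening (not assay) pipeline for cocaine in
powder samples measured by a handheld 785 nm Raman analyzer on a fixed
300–1,800 cm⁻¹ grid of 1,153 points (mean step 1500/1152 ≈ 1.302 cm⁻¹).
Detection rests on the spectral selectivity of the carbonyl stretch at
1,716 cm⁻¹ (cocaine HCl) / 1,712 cm⁻¹ (cocaine base): among common
cutting agents and adulterants, none has a band centered above
1,700 cm⁻¹, and only procaine has a band (near 1,690 cm⁻¹) that
overlaps the 1,700–1,728 cm⁻¹ region of interest from below.

## Preprocessing chains

Both chains use four primitives with fixed defaults:

| step | definition | default |
|---|---|---|
| SNV | (x − mean)/sd, sample (n−1) sd | per spectrum |
| SG  | Savitzky–Golay least-squares smoothing | window 9, order 2 |
| ROI | closed interval on the wavenumber axis | [1,700, 1,728] cm⁻¹ → 21 points |
| baseline | subtract the vector minimum | post-ROI |

Order matters and is the design point: the regression chain applies SNV
to the full spectrum *before* cutting the ROI, so diluent bands outside
the ROI keep shrinking the normalized cocaine peak as dilution grows —
this is what preserves concentration information. The discriminant
chain cuts the ROI first and normalizes only those 21 points, which
removes all concentration dependence and is therefore invariant to any
spectral change outside the ROI (a tested property).

Numerical choices: SG polynomial order is 2 (the conventional quadratic
default; the order is configurable). Edge points are handled by
evaluating the least-squares polynomial fit of the first/last window at
the edge offsets (`scipy.signal.savgol_filter(mode="interp")`), which
preserves exact reproduction of polynomials up to the filter order at
every point, including the short 21-point ROI vectors. SNV uses the
sample standard deviation and rejects zero-variance input. ROI bounds
are inclusive on both ends; this determines the 21-point feature count.
Baseline subtraction applies to the post-ROI vector in both chains.

## Outlier screen

Replicate scans of one sample are decomposed by PCA (SVD of the
column-centered matrix; component signs fixed by making each loading's
largest-magnitude element positive). The per-scan statistic is the
signed sum of the scores on the first three components; missing
components (fewer than 4 replicates) contribute zero. Scans whose
statistic falls strictly outside the central `coverage` (default 0.99)
empirical quantile interval of the pooled statistics are flagged and
excluded from model fitting. Because the statistic is signed, the
interval is two-sided; a one-sided cut on a signed score would be
direction-arbitrary. PCA is fitted within each unique sample's
replicates by default (`per_sample`); a `global` mode (one PCA over the
whole set) is provided. Samples with a single replicate are warned
about and never flagged. Flagging ≈1% of scans is the expected behavior
of the rule itself, not a data-quality statement.

## PLS models

Single-response NIPALS with column centering and no autoscaling
(spectra share units). For one response the component extraction is
closed-form per component — no convergence loop exists. Rank is checked
up front (`ncomp ≤ rank(X)`) and deflation guards against degenerate
score vectors. Fitted models are stored both in component form
(weights W, loadings P, y-loadings q, centers) and as the equivalent
regression vector `B = W(PᵀW)⁻¹q`; the two prediction routes agree to
numerical precision (tested). At full rank the PLS fit equals the
ordinary-least-squares fit, which the tests verify against a
normal-equations oracle and against scikit-learn's `PLSRegression` as an
independent implementation.

The production models are PLS-R (y = cocaine wt%, 4 components,
regression chain) and PLS-DA (y = 1 for either salt form, 0 otherwise,
2 components, discriminant chain). The PLS-DA "prediction" is the
continuous regression output on the 0–1 indicator; no probability
calibration is applied because the decision rule thresholds the raw
score.

Cross-validation forms 10 segments by shuffling the distinct replicate
groups (sample ids) with a seeded RNG and dealing them round-robin, so
replicate scans never straddle a training/held-out split; every
observation is predicted exactly once held-out, and RMSEP_cv is
reported per component count.

## Decision rule

Thresholds (0.8, 0.65, 30 wt%) are fixed constants of the method.
Rules are evaluated in order with first match winning; this resolves
the overlap between "PLS-DA ≥ 0.8 → positive" and "PLS-R ≤ 30 → negative"
in favor of the positive call, treating a high discriminant score as
sufficient on its own. The ambiguous interval is open at both ends:
exactly 0.65 is negative, exactly 0.8 is positive, and PLS-R must
strictly exceed 30 wt% for the rescue rule. The rule is exhaustive and
monotone in both scores (tested on a 201×201 grid).

An optional signal gate (off by default) returns "inconclusive" for
scans whose smoothed raw-ROI peak-to-trough range falls below
`inconclusive_snr` × a robust noise estimate (1.4826·median|Δ|/√2 of
first differences). The PLS pipeline itself never produces
inconclusives; the gate exists to emulate the no-match outcome of
field devices on misaligned, low-signal scans so confusion tables carry
the same three outcome categories.

## Evaluation

Confusion tables are 2×3 (cocaine / non-cocaine × positive / negative /
inconclusive). Rates are percentages rounded half-up to one decimal;
the denominator is either the tabulated row total or an explicit stated
count — both conventions are supported because published screening
tables sometimes state a sample count that disagrees with their own row
total (the retrospective table reproduced in the tests tabulates
1,390 + 174 = 1,564 negatives against a stated 1,393; the package
reports both rather than resolving the discrepancy).

False-negative curves are per (adulterant, cocaine level) over
cocaine-containing scans. Two inconclusive policies mirror field
practice: `include` counts inconclusives as FN over the full replicate
denominator; `exclude` drops them from numerator and denominator (an
operator would rescan). The LOD per adulterant is the lowest tested
level whose detection rate reaches the threshold (default 0.5, a
majority of replicates) and stays at or above it at every higher tested
level; "not reached" is an explicit sentinel. The majority definition
was chosen because screening practice speaks of a majority of false
negatives rather than a calibrated LOD; the threshold is configurable
and the estimate is monotone in it (tested).

## Synthetic data generator

Each compound is a list of Lorentzian bands (center, FWHM 8–15 cm⁻¹,
relative intensity), an optional broad Gaussian fluorescence background
(center 900 cm⁻¹, FWHM 1,500 cm⁻¹), and a cross-section multiplier.
A scan of composition `w` is

```
g · Σᵢ wᵢ·scaleᵢ·bandsᵢ(ν) + (offset + slope·(ν−300)) + Σᵢ wᵢ·fluorᵢ(ν) + ε(ν)
```

with log-normal gain `g` (σ = 0.3), uniform baseline offset
(20–150 counts) and slope (±0.01 counts/cm⁻¹), and i.i.d. Gaussian
noise (sd 25 ≈ 3% of a pure-cocaine band). Baselines stay positive so
the zero-clip never flattens a region. A `weak_scan_prob` fraction of
scans receives gain ×0.05 to emulate misaligned acquisitions (default
0). All randomness flows from one root seed through stable per-spectrum
sub-seeds hashed from (sample id, replicate), so generation order never
affects output.

Band centers for the diagnostic features follow published assignments;
relative intensities and cross-section scales are invented, versioned
fixtures (serializable as YAML). They were chosen so that the masking
structure of real mixtures is qualitatively reproduced: procaine's
near-ROI shoulder and strong scatter hide cocaine below ~40 wt%;
paracetamol's fluorescence suppresses regression-chain features;
weakly scattering diluents (inositol, lactose) leave low-level cocaine
detectable. Only orderings of FN rates and LODs are meaningful;
absolute synthetic LOD values are fixture-dependent by construction.

The panel generator reproduces the binary-mixture design exactly:
8 cutting agents × (1 pure agent + 9 mixtures at 10–90 wt% + 1 pure
cocaine slot) = 88 unique samples, each scanned tenfold by default.
The case-like generator draws purities from truncated normals
(HCl: mean 64.4, sd 15, range 19.1–85.5 wt%; base: mean 75.4, sd 12,
range 31.5–99.4 wt%; the sds are chosen, not published), splits the
remainder over 1–3 adulterants via a Dirichlet draw, and builds
negatives as pure adulterants, adulterant mixtures, or non-cocaine
drug profiles (ketamine-, amphetamine-, MDMA-like).

What the generator does *not* emulate: Poisson shot noise (noise is
additive and compound-independent, so fluorescence does not raise local
noise), instrument line-shape functions, cosmic rays, detector
saturation, colored/tablet samples, and SERS. Consequently, passing
tests demonstrate correctness of the pipeline's mechanics and the
qualitative masking structure, not field performance on real powders.

## Quantitation limits (a deliberate property)

Because the regression chain normalizes by the full-spectrum standard
deviation, the feature amplitude for a mixture with a weakly scattering
diluent saturates: above ~40 wt% cocaine the features become nearly
concentration-independent, and no linear model can recover composition
there (a test asserts this saturation). Accurate wt% recovery
(<5 wt% RMSEP_cv in the tests) is only possible for diluents whose own
out-of-ROI bands keep the normalization concentration-sensitive
(mannitol- and levamisole-like profiles). This mirrors the known
behavior of SNV-normalized single-window regression and is why the
pipeline uses the PLS-R output only as a thresholded indicator.

## On-disk formats

Spectrum sets round-trip losslessly through csv-wide (canonical),
csv-long, and a minimal JCAMP-DX subset (AFFN `(X++(Y..Y))` tables,
`##XUNITS=1/CM`, XFACTOR/YFACTOR honored; no SQZ/DIF compression, no
vendor binary formats). csv-wide headers carry wavenumbers at 10
decimals because 4 would alias grids that differ at the 1e-6 cm⁻¹
grid-matching tolerance; grids differing by more than that must be
resampled explicitly (`resample_linear`, interpolation only, no
extrapolation). Models serialize to versioned JSON; experiment configs
are YAML validated by pydantic; every run manifest records config,
config hash, seed and package version, which suffices to reproduce all
outputs bit-identically.

## Known limitations

* Absolute LODs, FN rates and case-screening rates on synthetic data are
  fixture-dependent; only within-run orderings are asserted.
* The HCl/base form label is carried in metadata but form
  classification accuracy is out of scope; truth is binary cocaine
  presence.
* Single-response PLS only; no multi-class discriminant analysis, no
  SIMPLS/kernel variants, no variable selection.
* The outlier rule's per-sample vs global reading and one- vs two-sided
  quantile are both implemented (defaults: per-sample, two-sided); real
  replicate data would be needed to adjudicate between them.
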