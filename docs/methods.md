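# Methods

Statistical model, estimators, simulation designs, and the numerical choices
behind `crekit`. Default parameter values given here are the package
defaults and the study conditions used by `analysis/` and
`scripts/acceptance.py`.

## 1. Guide effect sizes (`guide_effects`)

For a comparison of samples A and B (e.g. low vs high sorting bin, or a
timepoint vs plasmid), with raw counts `A_i`, `B_i`:

- **Mean-normalized log2FC** (default, `method="mean_norm"`):
  `e_i = log2((1 + A_i / mean(A)) / (1 + B_i / mean(B)))`.
- **Linear-scale log2FC** (`method="linear"`):
  `e_i = log2(((1 + A_i) / sum(1 + A)) / ((1 + B_i) / sum(1 + B)))`.

The pseudocount is 1 in both. The sign convention is
`A_enriched_positive`: guides enriched in the first sample of the
comparison get positive effects, so with the low bin first a knockdown
guide is positive. Per-replicate effects are averaged into a `mean` column;
guides with `A_i + B_i <` 10 reads in any replicate are flagged as dropouts.

## 2. Element calling (`element_caller`)

**Per-guide p-values.** A z-test calibrated on control guides:
`p_i = 2·Φ(−|e_i − μ₀| / σ₀)` with `μ₀, σ₀` the mean and SD (ddof=1) of
control effects. At least 30 controls are required; constant controls are an
error. Externally computed p-values may be supplied instead.

*Why safe-targeting controls.* Non-targeting guides have no genomic site, so
their effect distribution omits the targeting noise path (cutting/binding at
an inert locus, cell-state perturbation). Calibrating on them underestimates
`σ₀` and is anti-conservative. Safe-targeting guides pass through the full
noise path and are the default calibration set everywhere in the package
(with a fallback to the pooled controls when fewer than 30 are available).
In the default synthetic screen the safe/non-targeting variance ratio is
≈1.6 (Brown–Forsythe p ≈ 0.02), reproducing this concern.

**Footprint expansion.** Each guide's PAM interval is expanded to the
region it can plausibly perturb: ±10 bp for `cas9`/`dcas9`, ±150 bp for
`dcas9_krab` and activator modalities.

**Binning and aggregation.** The locus is tiled with zero-anchored 100-bp
bins. Each bin collects the p-values of all guides whose footprints overlap
it and combines them with Fisher's method: `X = −2·Σ ln p_i ~ χ²(2k)`.
For k = 2 guides (df = 4) the survival function has the closed form
`e^(−X/2)·(1 + X/2)`, used as an exactness oracle in the tests.

**FDR and merging.** Bin p-values are Benjamini–Hochberg adjusted
(`scipy.stats.false_discovery_control`); bins with FDR < 0.01 (and, when
effects are supplied, a consistent effect direction) are merged when
separated by a gap of at most one non-significant bin, yielding CRE calls
with mean effect and supporting guide counts.

**Outlier sensitivity.** Fisher's statistic is a sum of log p-values, so a
single extreme guide can carry a bin: e.g. three guides with p = 10⁻⁶ each
give X = 55.26, p ≈ 2.9·10⁻¹¹, while one p = 10⁻⁶ among two null guides
still reaches nominal significance. `element_caller` exposes a
leave-one-out sensitivity diagnostic so such single-guide calls can be
flagged; the off-target outlier test in `design_qc` (§5) addresses the main
biological cause.

## 3. Power simulation (`power_sim`)

Given measured per-guide effects of one element and control effects (both
centered on the control mean — the same calibration as the caller), the
simulation asks: with `n` guides per element, what fraction of `n_reps`
resamples detects the element at a target mean effect?

Per replicate, `n` element effects are drawn without replacement; they are
multiplicatively rescaled to each target mean
(`scaled_i = e_i · target / mean(e)`); a Welch t-test against the controls
is computed, optionally with a degrees-of-freedom override (`dof_override`)
replacing the Satterthwaite estimate; the p-value is Bonferroni-style
adjusted by `m_elements` and compared to `alpha` (default 0.05).

**Common random numbers.** The same drawn guide subsets are reused across
all effect targets for a given `n`, so the power curve in the target is a
per-draw monotone comparison rather than independent noisy estimates. This
is a variance-reduction choice; it does not change the estimand.

**Known artifacts of multiplicative rescaling (deliberate, documented).**
The Welch t statistic is invariant to rescaling the element sample when the
control variance term is negligible, while the Satterthwaite df *improves*
as the element is scaled down — so with estimated df, power can mildly
*decrease* in the target for heterogeneous elements. Separately, a drawn
subset with tiny sample variance inflates t regardless of target ("fluke
channel"), and flukes become rarer as n grows, so at sub-threshold targets
power can decrease in n. These are properties of the rescaling scheme, not
bugs; with a fixed conservative df (`dof_override=1`, mirroring common
practice for small guide panels) and controls that dominate the standard
error, both monotonicities are structural, which is the regime used in the
acceptance checks. The `analysis/04_power.py` grids use estimated df and
can show the mild non-monotonicities above.

## 4. Depth bootstrap and coverage titration (`depth_sim`)

**Depth.** For each target depth `d`, each sample's counts are resampled
as multinomial with `N_guides · d` total reads. Reported per depth over
`n_boot` bootstrap pairs: the dropout rate (guides under 10 reads) and the
Pearson correlation of `log2((1+A)/(1+B))` between all rep1×rep2 bootstrap
pairs, normalized to the same statistic at 5000× depth. Per-depth RNG
streams derive as `default_rng((seed, depth))`.

**Coverage.** Screens regenerated at 20/50/100/200 cells-per-guide
coverage are scored guide-by-guide against the planted elements (a guide is
positive iff its 3-bp PAM overlaps an element) with the area under the
precision–recall curve. AUPRC uses tie-grouped average precision
(identical to `sklearn.metrics.average_precision_score`, which the tests
use as an independent oracle; the implementation is self-contained).
Defaults give AUPRC rising 0.81 → 0.93 over 20× → 200× at prevalence 0.038.

## 5. Design QC (`design_qc`)

- **Filtering**: predicted specificity < 0.2, or a `TTTT` U6 terminator in
  the protospacer.
- **Off-target outliers**: control-calibrated 2σ outlier guides, cross-
  tabulated low- vs high-specificity × outlier/not (guides near true
  elements or DHS excluded), Fisher exact odds ratio. An all-or-nothing
  margin (one zero cell with hits present) reports an infinite OR. In the
  default synthetic library this test is *not applicable* — specificity
  annotations are Beta(8,1) so essentially no guide falls below 0.2, and
  the generator does not simulate off-target activity; the operation is
  validated on constructed examples instead.
- **Control variance**: safe vs non-targeting variance (Brown–Forsythe
  test, Welch mean test) and a subsample-size variance curve.
- **Selection strategies** (k guides per element): `closest` to the summit,
  `distal` at a fixed offset (179 bp), `every_nth` (evenly spaced distance
  ranks), and `random` (averaged over 100 draws). Ties break by guide id.

## 6. Strand bias (`strand_bias`)

Guides are placed in transcription coordinates from the PAM start relative
to the gene: promoter `−2000 ≤ u < 0`, gene body `2000 ≤ u ≤ length`.
A guide is *coding*-strand iff its strand equals the gene strand. Per
region, the coding/template ratio of mean knockdown with a Welch test;
cells with fewer than 5 guides are ineligible. In the generator, gene-body
template-strand guides keep `template_factor = 0.4` of the effect, so the
expected gene-body ratio is 2.5; the measured ratio on the default
strand-bias screen is 2.73 (p ≈ 10⁻⁶⁶), with promoter and outside regions
near 1.

## 7. Synthetic screens (`synthetic_screens`)

**Sorting model.** Expression is log-normal with scale
`sigma_expression = 0.5`; knockdown `e` shifts the log-mean by `ln(1−e)`;
sorting gates take the `bin_fraction = 0.10` tails, so
`p_low(e) = Φ(z + (−ln(1−e))/σ)` with `z = Φ⁻¹(0.10)` (and symmetrically
for high). Reads are multinomial per bin and replicate with
`depth = 500` reads/guide on average. Per-guide effects within a planted
element decay with distance (window 300 bp) plus guide-level noise
`sigma_guide = 0.03`; safe-targeting guides get small positive effects
(`sigma_safe = 0.05` half-normal-ish), non-targeting guides exactly zero.
Default locus: 30 kb, guides every 20 bp, elements `el_weak` [5000, 5400)
at 0.2, `el_mid` [12000, 12400) at 0.4, `el_strong` [20000, 20400) at 0.8,
plus 100 non-targeting and 100 safe-targeting controls, 2 replicates.

**Inversion.** `estimate_knockdown_from_bins` maps the observed
`log((A+0.5)/sum · sum/(B+0.5))` ratio — median-calibrated on
non-targeting guides — back to `e` through the model, via a 4000-point
grid of the monotone model log-ratio over `e ∈ (−0.9, 0.999)` and
`np.interp` (numerically identical to root-finding on this grid at ~30×
the speed). Recovery on the defaults: planted 0.2/0.4/0.8 →
estimated 0.21/0.45/0.68; the compression at 0.8 reflects the flattening
of `p_low` near complete knockdown plus finite-count saturation.

**Realism and limits.** The generator is deliberately minimal: no
off-target activity (specificity columns are annotations only), no
guide-efficiency covariates beyond distance decay, no overdispersion beyond
multinomial sampling, no chromatin context. It exists to give every
estimator a ground truth, not to fit any particular experiment.
One honest consequence: under a *count-level* null (shuffling counts rather
than effects), Fisher aggregation over correlated footprints can be
anti-conservative; the null calibration check therefore draws *effects*
from the control distribution, which matches the z-test's own model.
Generator defaults were fixed before results were inspected and are not
tuned to any outcome.

## 8. Numerical choices

- RNG: `numpy.random.default_rng` with tuple seeds `(seed, stream_id)` for
  independent substreams; every script derives all randomness from one
  `--seed`.
- p-value floor 1e-300 before `ln` in Fisher's method (a warning is raised
  when a clamped zero is encountered).
- BED score cap 320 (`min(320, −10·log10 p)` convention), `0 → p=1`,
  narrowPeak summit −1 → missing.
- Interval convention: half-open `[start, end)` everywhere; bins are
  zero-anchored so bin edges are reproducible across runs and loci.
- BH via `scipy.stats.false_discovery_control`; normal/χ² tails via
  `scipy.stats` survival functions (never `1 − cdf`).
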