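# Methods

## The index model

The WQI is a weighted arithmetic index over a configurable criteria set
(up to 40 parameters). Parameter *i* carries a positive weight *wᵢ* and
either an upper guideline limit *Lᵢ* (mg/L; NTU for turbidity) or, for pH
only, an acceptable band [6.5, 8.5]. For one record, availability is
resolved first: a parameter is usable iff it is globally included in the
criteria set, its per-record selection code is not −1 (struck for this
record) or 0 (declared missing), and a value is present. Record codes can
only narrow the criteria set — a globally excluded parameter cannot be
re-enabled per record. Blank/NA cells are treated as code 0 automatically;
requiring the analyst to type the 0 by hand would be strictly less usable
and is equivalent.

Weights are then renormalized proportionally over the usable set,
Wᵢ = wᵢ/Σⱼwⱼ. Proportional renormalization is the one choice that keeps
the index scale-invariant: a record at exactly its limits scores 100
whichever subset was measured. This is also why pH keeps its weight in
the denominator even when its quality value is zero inside the band —
availability, not score, drives the weighting. A record whose only usable
parameter is pH inside the band returns WQI 0 ("excellent") with an audit
warning, since that score reflects absence of evidence.

Quality values are qᵢ = (cᵢ/Lᵢ)·100·Wᵢ, with the banded pH rule
(0 in band, (6.5/pH)·100·W below, (pH/8.5)·100·W above; endpoints
inclusive, so the rule is continuous at the band edges up to the 100·W
factor). The WQI is Σqᵢ, classified on the five-band scale. The shared
band endpoints (50, 100, 200, 300) are resolved half-open [low, high),
with [300, ∞) mapped to "Unsuitable for drinking", making classification
total and deterministic on [0, ∞).

The default criteria set ships 13 drinking-water parameters with weights
pH 4, Ca 2, Mg 2, Cl 3, TDS 4, F 4, Mn 4, NO₃ 5, Fe 4, SO₄ 4, NH₄ 3,
Na 3, turbidity 4 (sum 46) and the usual guideline limits (e.g. nitrate
50 mg/L, TDS 1000 mg/L, turbidity 5 NTU). Total hardness is included in
the configuration but flagged excluded: it is a linear function of
calcium and magnesium and would double-count them; its weight (2) and
limit (500 mg/L) follow common hardness guideline practice since the
default set itself fixes neither.

## Descriptive statistics

`describe` reports the spreadsheet descriptive-statistics block: mean,
standard error sd/√n, median, sample standard deviation and variance
(n−1 denominator), range, min, max, sum, and a 95% confidence half-width
t₀.₉₇₅,ₙ₋₁·se. Percentiles (10/25/50/75/90/95) use linear interpolation
between order statistics with inclusive endpoints — the spreadsheet
convention, chosen because monitoring reports in this domain are
spreadsheet-shaped and fractional published quantiles indicate
interpolation. `class_shares` always reports all five labels, including
zero shares, so summaries are schema-stable.

## PCA validation

The validation stage asks whether the index tracks the dominant
hydrochemical gradients. Records are complete-case filtered (every
included parameter present; fewer than p+1 survivors is an error since
the PCA would be underdetermined). Columns are z-scored with the n−1
denominator and the correlation matrix is eigendecomposed
(`numpy.linalg.eigh`). Loadings are eigenvector·√eigenvalue, so column
sums of squares equal eigenvalues, row sums of squares are communalities
h² with uniqueness u² = 1 − h², and Σλ = p. Retention follows the Kaiser
criterion with a strict inequality (eigenvalue > 1); when nothing
qualifies the caller is told to pick k manually. Components are reported
unrotated — a varimax option exists for sensitivity checks (it preserves
h² but breaks the SS-loadings = eigenvalue identity). Eigenvector sign is
arbitrary, so each component is flipped to make its largest-|loading|
entry positive, giving reproducible output.

Scores are Z·v/√λ. Under ddof=1 z-scoring the sample variance of Z·v is
exactly λ, so the scores have exactly zero mean and unit variance. The
WQI is regressed (statsmodels OLS, intercept included, two-sided t
p-values) on the retained scores without standardizing the response;
with centered predictors the intercept then equals the WQI mean, which
makes the fit directly interpretable as "overall level plus gradient
contributions".

`proportion_var` divides SS loadings by the number of variables actually
supplied; `proportion_explained` divides by the total SS of the retained
columns.

## Synthetic data generator

The generator emulates a national drinking-water survey with a block
correlation structure: latent standard normals drawn with equicorrelated
blocks — salinity {Mg, Cl, TDS, F, SO₄, Na} at ρ = 0.85 (groundwater
mineralization), {Ca, Mn} at ρ = 0.6 (carbonate alkalinity),
{NO₃, turbidity} at ρ = 0.6 (domestic/agricultural surface impact), and
independent NH₄ (fertilizer signal), Fe and pH — then mapped through
exp(μ + σz) to strictly positive lognormal concentrations. Lognormal
marginals guarantee positivity and the right skew typical of
hydrochemistry. Medians sit at half the guideline limit (μ = ln(Lᵢ/2))
with σ = 0.6 on the log scale, so most synthetic samples classify
excellent/good with a right tail of degraded water. pH is drawn from a
normal (mean 7.5, sd 0.5 pH units) truncated to (0, 14] by rejection;
correlating pH with a lognormal block would require a copula map, so pH
must sit in a singleton block. Missingness is MCAR, independent per cell
at rate 0.05 by default — the weakest mechanism that still exercises the
dynamic-weight renormalization. The default sample count is 735, a
national-survey scale. Everything is reproducible from (config, seed) via
`numpy.random.default_rng`.

What the synthetic conditions do not emulate: spatial structure and
site-level clustering, seasonal trends, informative missingness (labs
skipping a parameter *because* it is extreme), censoring at detection
limits, and cross-block correlations. Tests passing on this generator
establish the algebra and the structure-recovery behaviour of the
pipeline, not distributional claims about any real survey.

## Numerical choices

- Dynamic weights sum to 1 within 1e−9 by construction; the engine agrees
  with the naive one-shot formula Σwᵢrᵢ/Σwⱼ·100 to 1e−9.
- Eigenvalues are clipped at 0 to absorb −1e−16-scale round-off from
  `eigh` on near-singular correlation matrices.
- Degenerate inputs fail loudly: constant columns (named), n ≤ p, missing
  cells in the PCA matrix, empty usable sets, rank-deficient regression
  designs, non-positive-definite block configurations (checked via
  Cholesky before any sampling).
- Report writing never rounds the "Original Data" part, so
  read → write → read is lossless; `--round` (default 2) affects only the
  derived parts.
- File formats: CSV (UTF-8, decimal point) and `.xlsx` workbooks, via
  pandas/openpyxl. Selection codes live in paired `<name>_code` columns.

## Known limitations

- The quality-value curve is linear in concentration with no sub-index
  rating curves or fuzzy memberships; parameters whose risk is strongly
  nonlinear near the limit are only crudely ranked.
- A WQI of 0 is reported when only in-band pH is usable; downstream
  consumers should heed the audit warning rather than the score.
- Kaiser retention is a blunt instrument on near-unit eigenvalues; the
  strict > 1 rule can flip a borderline component in or out between
  samples of the same population.
- Complete-case filtering before PCA discards roughly 1 − (1−r)ᵖ of
  records at MCAR rate r (about half at r = 0.05, p = 13); no imputation
  is attempted.
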