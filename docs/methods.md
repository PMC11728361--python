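# Methods

This note records what `echotex` computes, the conventions it pins
down, what the synthetic cohort generator does and does not emulate,
and the numerical choices behind the curve fit.

## The measurement model

All quantities are computed from the raw 8-bit pixel matrix of a
rectangular region of interest (ROI) drawn inside the muscle fascia
boundaries of a B-mode ultrasound image — no pre-processing, no masking
inside the rectangle. Coordinates are 0-based and half-open on both
axes, so a box's area is `(row_end − row_start) · (col_end − col_start)`;
boxes under 64 px are rejected because texture statistics on a handful
of pixels are meaningless.

### First-order features

The six histogram features are population moments (divisor *n*) of the
ROI intensities: echointensity `EI = μ`, variance `σ²`, standard
deviation `σ`, echovariation `EV = 100·σ/μ` (the percent coefficient of
variation), Fisher–Pearson skewness `g₁`, and Fisher excess kurtosis
(biased estimator, normal → 0). The ROI is the entire population of
interest, not a sample, which is why divisor-*n* moments are used; at
typical ROI sizes (~10⁴ px) the distinction is numerically irrelevant
anyway. EV is reported in percent — the per-grade cohort values
(67.28 down to 26.85) only make sense on that scale. For a constant ROI
(`σ = 0`), skewness and kurtosis are undefined; they are reported as 0
with a `degenerate` flag rather than NaN, and `EV = 0` exactly when
`σ = 0`.

Two invariances matter clinically and are enforced by tests: EV is
unchanged by multiplicative intensity rescaling (gain), which is the
argument for preferring it over EI across devices and settings; adding
a constant offset leaves `σ`, contrast and all run-length features
unchanged while strictly lowering EV.

### GLCM features

The grey-level co-occurrence matrix uses offset (0, +5) — distance 5 px,
angle 0° — with 256 levels, non-symmetric, normalised by the pair
count (`skimage.feature.graycomatrix`). Ten statistics are derived:
contrast, dissimilarity, homogeneity, ASM, energy = √ASM, max
probability, entropy, correlation, cluster shade and cluster prominence
(Conners form, `Σ p·(i+j−μᵢ−μⱼ)^k` with k = 3, 4). Conventions the
common libraries leave open are fixed as: entropy uses the natural log
over nonzero entries; correlation of a zero-variance marginal is defined
as 1 (the limit of a perfectly predictable texture, and the convention
of `graycoprops`). All ten are verified against naive double-loop
enumeration to 1e−12 on random small images.

### GLRLM features

Intensities are quantised to 16 equal-width bins by `⌊g·16/256⌋`. For
each scan direction a run-length matrix `r(g, l)` counts maximal runs of
equal quantised level; with `N_r` total runs and `N_p` pixels:
`SRE = (1/N_r)Σ r/l²`, `LRE = (1/N_r)Σ r·l²`, `GLU = (1/N_r)Σ_g(Σ_l r)²`,
`RLU = (1/N_r)Σ_l(Σ_g r)²`, `RPC = N_r/N_p`. The reported feature is the
arithmetic mean over **five** directions — 0°, 45°, 90°, 135° and 180°.
A 180° scan produces a matrix identical to 0°, so the five-angle mean
double-weights the horizontal direction; this mirrors the original
acquisition protocol exactly and is kept as the default, with
`angles=(0, 45, 90, 135)` available for the conventional average. Run
counting is verified exactly (integer equality) against a naive
line-walking oracle for every direction.

## The synthetic cohort generator

Real graded cohorts of spastic gastrocnemius are not publicly
shareable, so the generator produces images with the statistical
structure the analysis assumes, calibrated to the published per-grade
summary:

| grade | EV mean (%) | EV SD | EI mean | n  |
|-------|-------------|-------|---------|----|
| 1     | 67.28       | 15.05 | 60      | 24 |
| 2     | 46.62       | 7.17  | 105     | 58 |
| 3     | 37.16       | 4.94  | 150     | 24 |
| 4     | 26.85       | 4.06  | 195     | 24 |

EV means/SDs and group sizes are the published values; the EI means are
a modelling choice (only EI's direction — brighter with grade — is
reported), spaced so every EV target stays feasible in 8-bit range.
Per-image EV targets are drawn from `N(mean, SD²)` truncated to
(5, 150) %.

An image is built in four steps: (1) white Gaussian noise smoothed to
the configured correlation length (default 2 px) and restandardised;
(2) sinusoidal striation bands (period 14 px) added to the latent
field, scaled by `amplitude·(5−grade)/4` so fascicular banding is
strongest in healthy muscle; (3) a rank-based quantile transform maps
the latent field onto a beta distribution on [0, 255] whose moments
match the drawn (EI, EV) target — a Gaussian copula, preserving the
spatial structure while making the marginal exact; (4) an affine
touch-up to the exact target sample moments, clip to [0, 255], round.

The beta marginal is the load-bearing choice. A lognormal speckle
marginal — the textbook desk-scale stand-in — has a heavy right tail
that forces several percent of pixels past 255 whenever the target SD
is large relative to the headroom (e.g. grade 2 targets two SDs above
the mean), which would distort the extracted EV and trip the clipping
guard on ordinary cohorts. The beta family adapts its skew across the
intensity range (right-skewed near black, left-skewed near white, which
is also how bounded-dynamic-range B-mode images behave), reaches any
moment pair satisfying `σ² < μ(255−μ)`, and clips nothing. Targets
outside that bound are impossible for *any* distribution on [0, 255]
and raise a generation error naming the grade and target. The
post-round extracted EV is checked against the target (tolerance 1.5
percent-points; in practice the error is < 0.01).

Reproducibility: the cohort's EV targets are drawn first, directly from
`default_rng(seed)`, so the statistical stage can be reproduced without
rendering a single pixel; pixel noise comes from a second stream
derived from the same seed (`default_rng([seed, 1])`). A fixed seed
gives a byte-identical cohort.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: acoustic physics (point-spread
function, attenuation, time-gain compensation, fascia echoes); EI
variability *within* a grade (each grade has a fixed EI target, so the
synthetic EI–grade correlation is ≈ 1 rather than the ~0.87 seen
clinically, and GLCM/GLRLM features co-vary with grade only through the
speckle statistics); and rater behaviour beyond symmetric label noise.
Consequently the informativeness screen on synthetic cohorts selects
EI and EV with the correct directions but may also select other
features that track EV deterministically in this simplified texture
model — the published rater-count table remains the reference input for
the selection result itself.

## Statistics

Min-Max normalisation maps a column affinely to [0, 1] (constant
columns to 0); it is applied before correlation for scale
comparability and provably leaves Pearson r unchanged. Correlation
p-values are two-sided t-tests with n−2 df. Strength bands on |r| are
contiguous and half-open: ≥ 0.80 very strong, [0.60, 0.80) moderately
strong, [0.30, 0.60) moderate, < 0.30 weak (the source criteria leave
(0.50, 0.60) and the boundary points undefined; this closure is the
natural one). Grade is treated as a 1–4 numeric code in correlations —
the only reading under which the published r values are reproducible
from the group summary.

`pooled_pearson_from_group_stats` is the closed-form oracle: for groups
with sizes, means and SDs `(n_k, m_k, s_k)` at group values `g_k`, with
divisor-n moments, total variance = within + between and the covariance
depends only on group means, so the Pearson r of *any* dataset matching
those moments is obtained exactly. Applied to the table above it gives
−0.8086 → −0.81 at two decimals, independently confirming the reported
grade–EV correlation from the printed summary alone.

Group comparison: per-group descriptives use divisor n−1 (the reporting
convention for tables); the omnibus test is Kruskal–Wallis, or ANOVA
when every group passes Shapiro–Wilk at α = 0.05 (`method="auto"` — a
computable stand-in for histogram/Q-Q inspection); post hoc pairwise
comparisons are two-sided Mann–Whitney rank-sum tests with Bonferroni
correction `p_adj = min(1, 6·p)` for the six grade pairs. The paired
Wilcoxon variant is indefensible across independent groups of unequal
size and is not offered.

The two-limbs-per-subject dependence is deliberately ignored — the 130
ROIs are treated as independent, replicating the published analysis;
a mixed-effects treatment is out of scope and the limitation stands.

## The sorted-EV curve fit

Sorting the cohort's EV values in descending order and indexing them
x = 1..n (1-based, recorded in the result) yields a smooth decreasing
curve modelled as `y = a·e^(bx) + c·e^(dx) + E` with `b, d ∈ [−10, 0]`.
The slow term is structurally ill-conditioned: fits typically return a
huge `c`, a tiny `|d|` and `E ≈ −c`, which is numerically a straight
line — `(c, d, E)` is not identifiable and parameter values are not a
meaningful output. The contract is therefore *function-space*: the
fitted curve and its R², plus a `condition_flag` set when the
column-scaled Jacobian condition number exceeds 1e8. Evaluation uses
`a·e^(bx) + c·(e^(dx)−1) + (c+E)` (`expm1`) so the near-cancelling
`c + E` is computed once exactly; the naive form loses ~11 digits on
the degenerate parameter sets this model produces.

Initialisation is structured rather than guessed: a straight line
through the lower half of the curve gives `(c₀ = 10⁵, d₀ = slope/c₀,
E₀ = intercept − c₀)`; a log-linear fit to the upper-half residual
gives `(a₀, b₀)`; 20 starts jitter `(a₀, b₀)` multiplicatively with a
fixed internal seed and the best final SSE wins, making the fit
deterministic and permutation-invariant. On noiseless model-generated
data the curve is recovered to RMS < 1e−6 (the parameters are not, and
cannot be). Degenerate inputs fail loudly: constant input (SST = 0) and
n < 10 are errors, not silent NaNs.

## Problem sizes and defaults

Default cohort: 130 images of 128×128 px (24/58/24/24 per grade), seed
42. This is the published cohort's shape at a desk-scale image size —
large enough for stable texture statistics (16 384 px per ROI; the EV
standard error from speckle alone is ≪ the 1.5-point round-trip
tolerance), small enough that the full pipeline (generation, 21
features, selection, statistics, curve fit) runs in well under a
minute. The extreme size for the screen is k = 10; the simulated-rater
disagreement rate defaults to 0.

## Known limitations

* The rectangle-only ROI ignores that clinical ROIs avoid fascia by
  shape; users supply boxes already inside the fascia.
* Within-grade EI variation is not modelled (see above).
* The automatic quality-control step of excluding images with unclear
  fascia delineation has no computable rule and is not implemented;
  exclusion happens upstream of the cohort table.
* The 180° GLRLM direction duplicates 0° by construction; it is kept in
  the default average for protocol fidelity, not statistical merit.
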