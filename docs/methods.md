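# Methods

`droughtlight` implements the computational chain used to dissect
photosynthesis under drought stress in barley: JIP-test analysis of fast
chlorophyll-*a* fluorescence (OJIP) transients, differential-expression and
GO-enrichment calling, promoter scanning with position weight matrices, and
the designation of transcription-factor → photosynthesis-gene regulatory
pairs. Synthetic-data generators with planted ground truth stand in for raw
fluorimeter, microarray and RNA-seq data, so every stage is testable without
external downloads.

## OJIP transients and the JIP-test

A dark-adapted leaf exposed to saturating light shows a fast fluorescence
rise through the landmarks O (≈50 µs), K (300 µs), J (2 ms), I (30 ms) and
P (the maximum, F_M). The package reads F₀, F₃₀₀, F_J and F_I at these fixed
times — interpolating linearly in (ln t, F) when a trace is not sampled
exactly there, because OJIP curves are conventionally analyzed on log-time
axes — and takes F_M as the global trace maximum (P is defined as maximal
fluorescence, not the last sample). From

    V_J = (F_J − F₀)/(F_M − F₀),  V_I = (F_I − F₀)/(F_M − F₀),
    M₀ = 4 (F₃₀₀ − F₀)/(F_M − F₀)

the full Strasser-style parameter vector is derived: quantum yields
(φP₀ = 1 − F₀/F_M, φE₀, φR₀, φD₀, ψE₀, δR₀), specific fluxes per reaction
center (ABS/RC = (M₀/V_J)/φP₀, TR₀/RC = M₀/V_J, DI₀/RC, ET₀/RC), reaction
center density RC/CS₀ = F₀·φP₀·V_J/M₀, and the performance index

    PI_ABS = (φP₀ V_J / M₀) · [φP₀/(1 − φP₀)] · [(1 − V_J)/V_J].

The factored PI_ABS is algebraically identical to the expanded form
[1 − F₀/F_M]/(M₀/V_J) · (F_M − F₀)/F₀ · (1 − V_J)/V_J because
φP₀/(1 − φP₀) = (F_M − F₀)/F₀; the test suite asserts this and the other
internal identities (φP₀ + φD₀ = 1, ABS/RC = TR₀/RC + DI₀/RC,
ET₀/RC = TR₀/RC·ψE₀, RC/CS₀·ABS/RC = F₀) to 1e-12 relative on randomized
valid landmark sets, and cross-checks the worked example against an
independent sympy evaluation of the defining formulas.

Per-cross-section fluxes have no universally printed formula; the package
adopts the common F₀ proxy, ABS/CS₀ = F₀ (switchable to F_M), which makes
RC/CS₀·ABS/RC = ABS/CS an exact identity. The F_I time (30 ms) is taken
from the conventional start of the I–P phase; instrument software may use a
slightly different sample.

Relative variable fluorescence is V_t = (F_t − F₀)/(F_M − F₀) and the
differential curve is ΔV_t = V_t(treated) − V_t(control) on a shared
log-time grid. The sign convention is treated-minus-control, so
donor-side (OEC) stress appears as a **positive** ΔK band at 300 µs. Band
amplitudes ΔK/ΔJ/ΔI are ΔV_t read at the K/J/I times.

## Synthetic OJIP generator

The trace model is phenomenological, not a kinetic ODE model of PSII
electron transport:

    F(t) = F₀ + (F_M − F₀)·Σₖ ampₖ (1 − e^(−t/τₖ)) + K-band bump + noise,

with three saturating-exponential phases (amplitudes summing to 1, strictly
increasing time constants; defaults amp = 0.5/0.3/0.2, τ = 0.4 ms/8 ms/80 ms,
F₀ = 500, F_M = 2500 a.u., giving φP₀ ≈ 0.75–0.8 as in healthy leaves), a
Gaussian-in-ln-t K-band bump centred at 300 µs with σ = 0.35 ln-units
(local to ≈0.15–0.6 ms), and multiplicative Gaussian noise. Traces are
sampled on a 120-point log grid from 10 µs to 1 s that always contains the
four landmark times exactly, so landmark recovery on synthetic data needs no
interpolation (the instrument-data path interpolates). The grid size and
span are configurable; the schedule emulates PocketPEA-class instruments.
The "prolonged drought" preset scales F_M by 0.8, the I–P amplitude by 0.6
(renormalized) and injects a K band of 0.05 — tuning constants chosen to
qualitatively reproduce the stress signature (F_M depression, I–P loss,
positive ΔK), not measured values. Every simulator call takes one explicit
seed and returns a `SimTruth` with the analytic landmark values.

What the generator does **not** emulate: instrument saturation and detector
nonlinearity, the L/H bands, genotype-specific kinetics, or any mechanistic
QA/QB redox chemistry. Passing recovery tests therefore demonstrates the
correctness of the landmark/parameter algebra and its noise robustness, not
fidelity to any particular leaf.

## Differential expression

Counts are normalized with median-of-ratios size factors (geometric-mean
reference over genes positive in all samples). The DE statistic is a
transparent negative-binomial Wald test: per gene,
log2FC = log₂((m_B + c)/(m_A + c)) with pseudo-count c = 0.5 (avoids
infinite fold changes at zero means), standard error by the delta method
under the NB variance μ + αμ², and a two-sided normal p-value. The
dispersion α is estimated per gene by method of moments and floored at the
pooled (common) method-of-moments estimate across all genes. The floor is
the package's own choice: with 3 + 3 replicates the purely gene-wise
estimate has 4 residual degrees of freedom and is noisy enough to make null
p-values visibly anticonservative, while the common floor restores
approximate uniformity (measured fraction p < 0.05 ≈ 0.04 at 3 vs 3,
dispersion 0.05) without empirical-Bayes shrinkage. Replicating
edgeR/DESeq2 output exactly is a non-goal.

DEGs are called at inclusive thresholds |log2FC| ≥ 2 and BH-adjusted
p ≤ 0.01. BH and BY adjustments delegate to statsmodels. The synthetic
count generator draws gamma-distributed baseline means (shape 2, scale 250,
floor 5 — a realistic bulk-RNA-seq spread with many low-expressed genes),
plants a configurable fraction of genes with symmetric up/down effects, and
emits NB counts at the requested dispersion. Microarray-mode normalization
is the 75th-percentile shift (each sample's log2 intensities shifted so its
75th percentile is 0) followed by per-gene centring on the cross-sample
median.

Top-variance clustering ranks genes by cross-sample SD (ties broken
lexicographically by gene id, constant genes excluded), z-scores rows, and
runs either k-means (10 restarts, fixed seed) or average-linkage
hierarchical clustering on 1 − Pearson distance.

GO enrichment is the one-sided hypergeometric (Fisher) test per term over a
user-supplied gene → term table, restricted to terms with at least 5
background mappings, with Benjamini–Yekutieli adjustment (FDR under
dependency) at α = 0.05 by default.

## PWM scanning and exact p-values

Motifs are probability matrices read from MEME minimal files (additive
pseudocount 1e-4, renormalized). A window w scores
Σᵢ log₂(pwm[i][wᵢ]/bg[wᵢ]) bits; both strands are scanned, offsets are
0-based on the + strand of the supplied sequence, and windows containing N
are skipped. Scores are discretized to a 1/1000-bit grid and the null
distribution of the discretized score under the background model is built
by exact dynamic-programming convolution of per-position distributions; the
p-value of a hit is the tail P(score ≥ s). On the shared grid the DP equals
exhaustive 4^L enumeration to machine precision (verified for every
packaged motif, all widths ≤ 8). Relative to *continuous* scores the
deviation is bounded by the background mass of words within L/2000 bits of
the threshold; for motifs whose columns take few distinct values, tied word
scores can concentrate mass at single points, so the continuous-score
comparison is asserted as a two-sided sandwich bound rather than a fixed
epsilon. Overlapping hits of one motif on one promoter are collapsed to the
best-p hit (one site, one count); q-values are BH over all scanned windows
per motif/sequence. Per-hit FDR estimation by bootstrap is not implemented
(not reproducible from a fixed description); BH is used instead.

Regulatory pairs: hits in promoters of photosynthesis-related genes
(promoter = 1500 bp upstream by default, configurable) are mapped to TFs
through an explicit motif → TF table; a pair is emitted for every
(DEG-encoded TF, target gene) with at least one supporting hit, carrying
both fold changes and FDRs, sorted by TF fold change ascending. The
packaged 17-row pair table ships as a verbatim in-package fixture; the
packaged motif file is a small synthetic stand-in set (named as such), not
a redistribution of any motif database.

## Group statistics

One-way ANOVA with Tukey HSD via the studentized-range distribution
(Tukey–Kramer SE for unbalanced groups), with a compact letter display
assigned by insert-and-absorb over the significant-difference graph, groups
ordered by mean descending. Pairwise p-values are cross-checked against
statsmodels' `pairwise_tukeyhsd` in the tests. Correlations are reported as
signed R² = sign(r)·r², so negatively correlated parameter pairs carry a
negative sign. qPCR fold change is FC = E^(−ΔCt) with ΔCt = Ct(treated) −
Ct(control); reference-gene (ΔΔCt) pre-subtraction is available but off by
default, since the printed formula omits it. Water loss is
WL = Dw·100/Fw with a `reached_target` flag at the 30%-loss stop rule.
Only the one-way, per-timepoint ANOVA is implemented; factorial (two-way)
designs are out of scope.

## Problem sizes and numerical choices

The test and acceptance runs use 2000 genes at 3 vs 3 replicates with 5%
planted DEGs at log2FC 4 ("4-fold" in the log2 convention used for DEG
thresholds) and NB dispersion 0.05; 10,000 randomized landmark sets for the
algebraic identities; 50 traces at 1% noise for φP₀ recovery; exhaustive
4^L enumeration for all packaged motifs; and backgrounds up to N = 30 for
the enrichment brute force. A planted log2FC equal to the calling threshold
(log2FC 2) is not recoverable at ≥90% by construction — the estimate is
centred on the threshold — which is why the recovery benchmarks plant a
4-log2-unit effect. Degenerate inputs (flat traces, V_J ∈ {0,1}, all-zero
samples, constant series) raise typed errors rather than NaNs. All
randomness flows from explicit integer seeds; repeated runs are
byte-identical.

## Known limitations

- The OJIP simulator is phenomenological; it cannot validate mechanistic
  interpretations of JIP parameters.
- The NB Wald test has no fold-change shrinkage; very-low-count genes rely
  on the pseudo-count and the dispersion floor.
- Compact letter displays are not guaranteed minimal in pathological
  significance graphs (insert-and-absorb heuristic).
- The regulatory-pair stage predicts binding sites, not regulation;
  orthology-based motif projection and TF-family classification from
  protein domains are out of scope (annotation tables are inputs).
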