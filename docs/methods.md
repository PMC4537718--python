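# Methods

## Count model and the per-bin exact test

A two-condition MeRIP-Seq comparison provides four libraries: untreated
input and IP with depths N0 and M0, treated input and IP with depths N1
and M1. Every methylation site is divided into N ordered, equally sized
bins; bin n carries counts (x0, y0, x1, y1). Counts are modelled as
Poisson with bin-specific rates proportional to library depth; the IP rate
additionally carries the within-bin methylation proportion η. The question
"did η change between conditions?" conditions away the unknown rates:
given the per-condition totals t0 = x0 + y0 and t1 = x1 + y1, each input
count is binomial, and when the depths satisfy N1·M0 = N0·M1 equality of
methylation proportions is exactly independence in the 2×2 table. The
balance is established by rescaling **one** sample — the treated IP: its
depth becomes M1′ = N1·M0/N0 and its counts are multiplied by
ρ = N1·M0/(N0·M1) and rounded to the nearest integer (floored at 0).
Fixing which sample is rescaled makes results deterministic.

Under the null, x0 follows Hypergeometric(N = t0+t1, K = x0+x1, n = t0).
The two-sided p-value uses the minimum-likelihood rule: the sum of all
point masses not exceeding the observed mass times (1 + 1e-7), the
convention shared by the classical exact-test implementations. The
implementation anchors one log-pmf evaluation per table and extends it
across the whole support with the exact pmf ratio recurrence accumulated
in log space, which keeps ~10^5 tables per second tractable at any depth;
accumulated rounding is of order (support width)·machine-epsilon, far
inside the 1e-12 agreement the test suite demands against direct
enumeration. Two-sided sums that underflow entirely are floored at 1e-300
so downstream logarithms stay finite. All-zero tables get p = 1 and a
`degenerate` flag but stay in sequence so HMM chains remain unbroken.
FDR is Benjamini–Hochberg, computed in one pass across all bins of all
sites: the pooled FastFHC estimate requires a common FDR scale, and a
genome-wide adjustment is also the convention users expect. No
pseudocount is added by default (`test_pseudocount = 0`).

## Hidden Markov smoothing

The hidden state s_n ∈ {0, 1} (1 = differentially methylated) follows a
first-order chain with initial distribution π and row-stochastic 2×2
transition matrix A. The reported quantity is the posterior
γ_n(1) = P(s_n = 1 | O) from forward–backward decoding — not a Viterbi
path, since a per-bin probability is what downstream DMR calling
thresholds.

Numerics: per-step rescaled (Rabiner) forward–backward rather than
log-space, because the scaled form yields the two-slice marginals ξ
directly; the test suite cross-checks it against an independent log-space
implementation on 3000-step chains (agreement 1e-8) and against exhaustive
2^N path enumeration for N ≤ 8 (agreement 1e-10). The kernel is compiled
with numba when available, with a pure-numpy fallback of identical
semantics.

Baum–Welch EM re-estimates π ← γ_1, A_ij ← Σξ_n(i,j)/Σγ_n(i), and — for
the binary-observation model — a single symmetric Bernoulli correctness
probability p (the posterior-weighted agreement rate). p is projected onto
[0.5, 1 − 1e-6] each M-step: the symmetric emission with p ≥ 0.5 pins
state 1 to "differential methylation" and removes label switching. The
projection is the constrained M-step optimum of a concave objective, so
the EM monotonicity guarantee survives it (verified over 200 seeded runs,
slack 1e-9). Convergence: relative log-likelihood change below
tol = 1e-6, max_iter = 100. Initialisation is seeded: π = (0.5, 0.5),
diagonal of A ~ U(0.6, 0.95), p ~ U(0.7, 0.95), one spawned RNG substream
per site so results are reproducible and independent of site order.
Fixed emission rows are clipped to [1e-10, 1 − 1e-10].

## The three strategies

* **FHB** — binarise the genome-wide FDR at a cut-off (default 0.05,
  strict `<`), treat the 0/1 calls as noisy observations, fit (π, A, p)
  per site by EM.
* **FHC** — skip binarisation: emission row n is (p_n, 1 − p_n), reading
  the exact-test p-value as the likelihood of the bin under "no change".
  EM updates π and A only; the emission is never re-estimated.
* **FastFHC** — binarise as in FHB, then estimate π (the genome-wide
  differential fraction) and A (transition counts within sites only,
  additive pseudocount 1 per cell to avoid degenerate rows; the paper-free
  choice here is the pseudocount, which matters only when a state is never
  observed) in a single pooled pass, and run one E-step per site with the
  FHC emission rows. No per-site iteration.

Sites with fewer than `min_bins_for_em = 5` bins cannot support per-site
EM; FHB and FHC report 1 − p_value as a posterior surrogate there and set
an `em_fallback` flag. FastFHC needs no fallback — pooled parameters plus
a single E-step are well defined down to one-bin sites, which is precisely
its design motivation.

DMR reporting is a thin layer: bins with posterior ≥ cutoff (default 0.9)
are merged into maximal runs within a site; each DMR records its bin span,
mean/min posterior, best p-value, and a direction taken from the sign of
the summed finite per-bin log2 odds ratios (the HMM state itself is
directionless, covering hyper- and hypo-methylation alike).

## Synthetic data generator

The generator emulates the binned four-sample count structure of a
two-condition MeRIP-Seq comparison with spatially coherent differential
methylation. Defaults are the benchmark's study conditions: 100 sites of
1000 bins; all four depths 1e8; normalised input Poisson mean λ0 = 1e-6
(≈100 reads per bin per library); hidden states from a chain with
π = (0.5, 0.5) and self-transition probability 0.9 (0.95 in the
increasing-length benchmark); per-site differential expression
d_g ~ U[−3, 3] in log2, applied to both treated libraries; per-bin
methylation effect m_n ~ U[−3, 3] in log2 on differential bins, exactly 0
elsewhere.

How m maps to counts is governed by `dm_effect`. The default,
`count_odds_ratio`, multiplies the treated IP mean by 2^m, which makes the
expected odds ratio of the tested 2×2 count table equal 2^m exactly — the
literal reading of "read-count log2 odds ratio", and the construction
under which the unsmoothed test's benchmark AUC (~0.90) matches the
reference value this package is checked against. The alternative
`proportion_odds_ratio` applies the odds ratio to a baseline methylation
proportion η0 (default 0.5) and multiplies the IP mean by the resulting
proportion shift; it compresses effect sizes (the IP multiplier is bounded
by 1/η0) and yields a markedly weaker raw-test AUC, so it is not the
default. Both are identity at m = 0.

What the generator does **not** emulate: biological replicates and
overdispersion (counts are exactly Poisson), read-level artefacts
(mappability, fragment-length, GC), isoform structure, and
non-uniform background λ0 along a site. Passing benchmarks therefore
demonstrate correctness of the inference machinery under the stated
generative model, not performance on real libraries, where
extra-Poisson variance will inflate the raw test's optimism.

## Evaluation harness

Scoring is per bin: the HMM strategies by posterior, the raw-test baseline
by 1 − p. AUC is the normalised Mann–Whitney statistic (ties one half),
computed via ROC integration and verified against a pairwise-comparison
oracle. The sweep harness varies one factor at a time — FDR cut-off
(analysis knob: all levels see identical datasets), generating
self-transition probability, common depth, or the treated-IP depth alone —
over seeded datasets and returns a tidy table.

Problem sizes in the test suite are chosen to keep the default run fast:
the benchmark reproduction uses the full 7-site 50–350-bin setting with 10
datasets, while the repeated-simulation checks (null control, factor
trends) use 20 sites × 250 bins per dataset — thousands of bins per
dataset, enough that Monte-Carlo error stays inside the asserted
tolerances.

## Known limitations

* No replicate-aware dispersion model; variance is Poisson by assumption.
* Exactly two conditions and two hidden states; no covariates.
* Counting reads into bins and peak calling are upstream of this package.
* The p-value-emission likelihood (p, 1 − p) is a heuristic, not a
  calibrated null/alternative likelihood pair; its smoothing strength
  depends on how extreme the p-values are, and on deeply sequenced data
  the binary-observation strategy can outperform it.
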