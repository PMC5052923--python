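# Methods

## Motifs and statistics

A motif is a gapless alignment of `N` DNA sequences of common width `L`,
treated extensionally (the sequences themselves, not a probability-matrix
summary).  All statistics use plug-in (maximum-likelihood) column base
frequencies with **no pseudocounts**, and all entropies and ICs are in
bits (log base 2):

* total positional entropy `H(M) = −Σ_c Σ_b p_c(b) log2 p_c(b)`, with
  `0·log 0 ≡ 0`;
* information content `IC(M) = 2L − H(M)`, i.e. the reduction from a
  uniform mononucleotide background of 2 bits/base; per-column IC is
  `2 − H_c ∈ [0, 2]`;
* the informational Gini coefficient (IGC) of the sorted per-column IC
  vector `c_1 ≤ … ≤ c_L`: `G = 2Σ_j j·c_j / (L Σ_j c_j) − (L+1)/L`.
  For finite `L` its maximum is `(L−1)/L`.  When total IC is exactly zero
  the formula is 0/0; we return 0 with a warning, reading an all-uniform
  motif as maximally even.
* GC fraction: (count of G + C) / (N·L).

Sequences are kept in input order, but every statistic is invariant under
row permutation.  Ambiguity codes and gaps are rejected rather than
imputed: the sampling model has no provision for them, and silently
imputing would change the statistics being matched.

## Count-vector classes

A column's entropy depends only on its base counts `(n_A,n_C,n_G,n_T)`,
and only through their multiset.  Columns therefore collapse into classes
indexed by the integer partitions of `N` into at most 4 parts — counted in
closed form by `round(((N+4)³ + 3(N+4)² − 9(N+4)((N+4) mod 2))/144)`,
which is O(N³) (59,823 classes at `N=200`).  The canonical representative
is the count vector sorted non-increasing (any fixed total order would
do).  The class weight

`w(n̄) = (4!/∏_v m_v!) · (N!/∏_b n_b!)`

factors into the number of distinct assignments of the count multiset to
bases times the number of row arrangements per assignment; weights are
kept as exact big integers (used verbatim for the completeness identity
`Σ w = 4^N`) and as log-gamma floats for tilted sums — the two paths are
cross-tested to 1e-9 relative.  The single-column partition function
`Z_c(λ) = Σ w(n̄) e^{−λH(n̄)}` and the tilted mean/variance/skewness of
column entropy are log-sum-exp sums over classes, safe for any |λ| a float
can hold.  The tilt convention is `e^{−λH}` with `H` **in bits**; users
comparing λ against natural-log implementations must rescale by ln 2.

Alphabets other than DNA are supported generically (factors of 4 become
|A|), but the class count grows as O(N^(|A|−1)), so a warning fires above
|A| = 6.

## MaxEnt sampling

The maximum-entropy distribution over motifs subject to a mean-entropy
(equivalently mean-IC) constraint is `P(M) ∝ e^{−λH(M)}`.  Because
positional entropy is additive, it factors column-wise with `Z = Z_c^L`,
and sampling a motif is sampling L independent columns.  Tuning solves
`⟨IC⟩_λ = target` by bracketed Brent root-finding (initial bracket
[−1, 1], doubled until it straddles; guaranteed because the tilted mean is
strictly monotone in λ).  The convergence tolerance is stated on the mean
IC in bits (1e-10), not on λ.  Feasible targets form the open interval
`(L(2 − H_max(N)), 2L)` where `H_max` is the entropy of the most balanced
partition; endpoint targets are rejected with the interval in the error.

A column is drawn in three exact stages: (1) class by inverse-CDF lookup
in the precomputed tilted class probabilities; (2) a uniform choice among
the distinct assignments of the count multiset to bases, implemented as a
uniform random permutation of the counts (every distinct assignment arises
from the same number of permutations); (3) a uniform shuffle of the letter
multiset over the N rows.  The product of the stage probabilities cancels
`w(n̄)` exactly, so every motif's probability depends on its entropy only
— the sufficiency requirement of the sampling problem.

Seeding: one user seed spawns an independent substream per motif
(`SeedSequence.spawn`), so output i is reproducible and independent of how
many motifs are requested.  The IC-only fast path used by importance
sampling and the validation grids draws class indices from a single
vectorized stream (also seed-deterministic).

## Truncated-uniform sampling

The TU target is uniform on `{M : |IC(M) − I| ≤ ε}`.  The proposal is the
MaxEnt distribution with mean IC `I`; in IC form `Q(M) ∝ e^{λ IC(M)}`, so
the density ratio is `∝ e^{−λIC}`, maximized at the lower band endpoint
for λ > 0.  The acceptance ratio is `AR(M) = e^{λ(I_min − IC(M))}`, never
below `e^{−2λε}`; for λ < 0 (bands below the uniform mean) the maximizer
is the upper endpoint and the constant uses `I_max` symmetrically.
Out-of-band proposals have target density zero and are rejected before the
ratio test.  Rejection only ever inspects class indices; letters are
materialized for accepted draws alone.  A budget guard (10⁶ proposals per
motif) turns pathological parameter choices into a diagnostic error rather
than an endless loop.

Balancing proposal cost (∝ 1/ε) against mean trials (≤ e^{2λε}) gives the
runtime-optimal half-width `ε = 1/(2λ)`; it diverges as λ → 0, where any ε
is cheap, so the default caps at 0.5 bits for |λ| < 1.

**Acceptance-rate accounting.**  The sample report carries two rates, and
the distinction matters.  The *ratio-test rate* conditions on proposals
that land in the band; its mean is ≈ `(1 − e^{−2λε})/(2λε)` and it stays
above 10⁻² across the entire practical parameter range (it is ~1/7 at
λ ≈ 35, ε = 0.1).  The *overall acceptance rate* also counts out-of-band
proposals and is bounded above by the proposal's band mass, which shrinks
like `ε/σ` as N grows (σ² = L·var of column entropy ∝ L/N): at L = 10,
ε = 0.1 it falls from ~3×10⁻² at N = 20 to ~2×10⁻³ at N = 200.  Runtime
scales with the overall rate; statements that acceptance "stays above
10⁻²" can only refer to the ratio-test stage.

Because motif density decays roughly exponentially in IC, the TU
distribution is biased toward the lower end of its band — visibly so for
large N and wide bands (mean sampled IC ≈ 9.5 for N = 200, I = 10,
ε = 0.5).  This is a property of the target distribution, not a sampler
artifact.

## GC-content control

The two-constraint model fixes mean IC and mean GC.  Column entropy
depends only on the count multiset while GC depends only on which counts
sit on G and C, so the fit decomposes: λ is tuned first, exactly as
above, and the GC conjugate parameter μ is then tuned by one-dimensional
root-finding on the exact expectation

`⟨GC⟩ = Σ_n̄ P_λ(n̄) · Σ_g g·u(g|n̄) e^{−μg} / Z(n̄, μ)`,

where g ranges over GC fractions realizable by assigning the multiset to
bases and `u(g|n̄)` is the fraction of distinct assignments with that g.
Sampling replaces only stage 2 of the column sampler (assignment drawn
with probability ∝ `e^{−μg}` among the ≤ 24 distinct assignments); stages
1 and 3 are untouched, so the entropy-class marginal — and hence the IC
distribution — is *exactly* invariant under GC tilting.  Note this
composition is deliberately not the raw joint tilt
`∝ e^{−λH + μ'·GC}`, whose class marginal would shift with μ'; the
composition preserves both the tuned IC and the sampler's efficiency.

`g` is a fraction, `(n_G + n_C)/N`, so negative μ raises GC under the
`e^{−μg}` convention; the API is phrased in terms of the target fraction
and hides the sign.  Feasibility: the attainable mean-GC interval is the
λ-weighted average of each class's extreme realizable g (two smallest vs
two largest counts on the GC pair); a fully conserved ensemble spans
[0, 1], a maximally balanced one collapses to {0.5}.  Targets outside the
interval raise an error naming it.

## Bootstrap percentiles

For observed motif M and statistic f, replicates are drawn i.i.d. from
the chosen null (MaxEnt at mean IC = IC(M), or TU centered there with the
1/(2λ) default ε, logged and recorded), and the percentile is the
fraction of replicates with f strictly below f(M).  Ties therefore lower
the percentile; an off-by-default midrank option counts half of each tie.
Any deterministic Motif → real function can be registered by name; IC,
IGC and GC ship.  Motifs whose IC sits exactly on the achievable-range
boundary (e.g. perfectly conserved) admit no MaxEnt proposal and are
rejected with a pointer toward an explicit TU band.  For motifs drawn
from the null itself, percentiles of a continuous statistic are
approximately uniform on [0, 1] (verified by KS test in the suite).

## IC p-values

With Q the MaxEnt distribution tuned so `⟨IC⟩_Q = I`, the uniform-null
tail probability `p = Pr(IC(M) > I)` (strict inequality; ties live on
measure-zero class boundaries) is the importance-sampling identity
`p = (Z_Q/Z_P)·⟨[IC > I] e^{−λIC}⟩_Q` with `Z_P = 4^(NL)` and
`log(Z_Q/Z_P) = 2λL + L·log Z_c(λ) − NL·log 4`.  Three estimators, all
end-to-end in log10:

* **bound**: `(Z_Q/Z_P)·½·e^{−λI}`.  The envelope `e^{−λI}` is exact for
  λ ≥ 0; the ½ assumes the tilted IC distribution is symmetric about its
  mean and is flagged as heuristic in the result metadata whenever the
  exactly-computed skewness exceeds 1 in magnitude.  For λ < 0 the
  envelope argument fails (a warning fires); p > ½ there anyway.
* **moment**: the bound times `erfcx(λσ/√2)`, from integrating
  `e^{−λx}` against a normal density with the exactly computed variance
  σ² = L·var(H).  This is the workhorse: it tracks importance sampling
  within ~0.3 log10 units over every dimension we test, down past
  10⁻⁵⁰⁰.
* **importance sampling**: n draws of IC from Q (class indices only),
  log-sum-exp average, delta-method SE on the log10 scale.  Zero tail
  hits return −∞ with a warning to increase n.

The bound exceeds the truth by exactly the reciprocal erfcx factor,
≈ λσ·√(π/2) for large arguments.  At L = 10 and N between 20 and 100 this
is a factor of 4–200, growing with λσ — the bound is a genuine bound but
not a tight one at realistic motif dimensions, and consumers should prefer
the moment or IS estimates whenever a two-sided answer is wanted.

E-values under the OOPS (one occurrence per sequence) data model multiply
p by `∏_i (m_i − L + 1)` alignments; other alignment-count models are out
of scope.

The same machinery counts motifs in an IC band:
`#{M : |IC − I| ≤ ε} = Z_Q·⟨[band] e^{−λIC}⟩_Q`, with a moment-matching
analogue integrating over the band; the two agree within ~0.1 log10 units
on the 20×10, 10 ± 0.1-bit case (≈ 10⁷⁸·⁵ motifs).

## Validation harness and synthetic data

All testing is synthetic; the generators are the samplers themselves plus
exhaustive enumeration:

* **Oracles**: every motif of dimension N×L enumerated (guarded at
  4^(NL) ≤ 10⁶) with entropies; class-based Z, moments and exact tail
  probabilities must match to 1e-9.  Class probabilities are also derived
  independently by enumerating the 4^N single columns.
* **Sampled-IC grid**: L = 10, N = 20, 40, …, 200 (the 20-site step is a
  harness choice), targets 5/10/15 bits, ε = 0.1, 100 motifs per cell,
  per-cell seeds recorded; MaxEnt cell means within 3·SD/√100 of target,
  TU draws all in-band, both acceptance rates reported.
* **IGC given IC**: N = 50, L = 10, total IC stepped 0.1–19 bits over 100
  steps, 100 motifs per sampler per step; per-step Kruskal–Wallis with
  Benjamini–Hochberg FDR control at 5%.  The two samplers are
  statistically indistinguishable up to the ~5% false-discovery allowance
  (a hard ±0.1-bit band and a ±~1-bit MaxEnt spread do induce a tiny real
  difference detectable at a few steps with enough power); mean and
  variance of IGC both fall monotonically with IC, and IGC → 0 as columns
  saturate at 2 bits.
* **P-value comparison**: L = 10, N ∈ {20, 50, 100}, IC 2–19 bits;
  empirical CCDF from 10³ uniform draws down to its 10⁻³ detection limit,
  importance sampling (10³ draws per point) beyond.

These experiments emulate ensembles of *null* motifs.  They do not
emulate real binding sites — no phylogenetic correlation between sites,
no positional dependence, no alignment error, no biased base composition
unless GC control is requested — so passing them demonstrates the
correctness of the null machinery, not any claim about biological motifs.

## Numerical choices

* All tilted sums in log space (log-sum-exp); no quantity underflows for
  p-values past 10⁻⁵⁰⁰ or |λ| ≤ 500 at N ≤ 500.
* Brent root-finding with xtol 1e-13 / near-machine rtol for both λ and
  μ; achieved means re-verified against the stated bit-scale tolerances.
* Inverse-CDF class sampling by binary search on cumulative
  probabilities, with the final CDF entry pinned to 1.0 so a uniform draw
  of exactly 1−ulp cannot fall off the table.
* Exact factorials (big int) everywhere they are asserted exactly;
  log-gamma otherwise.
* Degenerate inputs: zero-IC motifs (IGC warning + 0), boundary IC
  targets (feasibility errors naming the interval), empty motif lists
  (errors), λ = 0 ε-heuristic (capped with warning).

## Limitations

* Class enumeration is O(N³) for DNA and O(N^(|A|−1)) generally; very
  deep alignments should be downsampled (statistics of column-wise IC and
  IGC move by O(1/N) under random downsampling, < 0.01 bits/position at
  N = 200).
* Only the OOPS alignment count is implemented for E-values.
* No continuous-limit (probability-simplex) sampler: exact sampling for
  entropic priors over the simplex is an open problem, and the discrete
  machinery here does not pass to that limit.
* The analytic p-value bound is loose at realistic dimensions (see
  above); it is retained for its independence from the normality
  assumption, not as a point estimate.
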