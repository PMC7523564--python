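# Methods

## Model

We consider a diploid, biallelic autosomal locus with focal-allele
frequency `p` at birth. One episode of sex-specific viability selection
with genotype fitnesses `1+s_j : 1+s_j h_j : 1` (sex `j ∈ {f, m}`) changes
the frequency among breeding adults to

```
p_j' = [p²(1+s_j) + p(1−p)(1+s_j h_j)] / w̄_j        (exact recursion)
p_j  ≈ p + s_j p(1−p)[h_j + p(1−2h_j)]               (first order in s)
```

Both forms are exposed (`breeding_freqs_exact`, `breeding_freqs_approx`).
The exact recursion is the default inside the power and `s_min`
calculators because it stays valid at the strong selection needed by
small-sample designs; the first-order expansion is retained because the
analytic results downstream are built on it, and the two agree to
`O(s²)` (property-tested for `|s| ≤ 0.01`).

Sex-biased migration produces the same observable through
`p_j = (1−m_j) p + m_j p̃`, with the identity
`p_f − p_m = (m_f − m_m)(p̃ − p)`: between-sex differentiation without any
sex difference in selection. This is why the scan treats structure
scenarios as first-class artifacts.

Random mating of breeding adults gives offspring genotype proportions
`(p_f p_m, p_f(1−p_m)+p_m(1−p_f), (1−p_f)(1−p_m))`; the population
heterozygote excess `F_IS = P_Aa/(2p̄(1−p̄)) − 1` equals the parental
between-sex `F_ST = (p_f−p_m)²/(4p̄(1−p̄))` exactly (enforced as a test
identity).

## Sampling distributions

With `k_j ~ Binomial(n_j, p_j)` gene sequences per sex, Nei's plug-in
estimator `F̂_ST = (p̂_f−p̂_m)²/(4p̂(1−p̂))` satisfies, approximately,

* null (`p_f = p_m`): `2 n_H F̂_ST ~ χ²(1)`, `n_H = 2(1/n_f+1/n_m)⁻¹`;
* alternative: `c·F̂_ST ~ χ²(1, λ)` with
  `λ = (p_f−p_m)²/(p_f(1−p_f)/n_f + p_m(1−p_m)/n_m)` and
  `c = 4 n_f n_m p̄(1−p̄)/(n_m p_f(1−p_f) + n_f p_m(1−p_m))`;
  under the null with equal sample sizes `c` reduces to `2 n_H`.

An offspring cohort of `n` genotypes gives
`F̂_IS ~ Normal(1/(2n) + F_ST_parents, 1/n)` for large `n`. The `+1/(2n)`
null mean and the `1/n` variance were verified by Monte Carlo (10⁵
cohorts) before being frozen into tests. F̂_IS testing is one-sided
(upper tail): the signal term is a square and can only elevate the mean.

The χ²(1) approximation degrades for small per-sex sample sizes or rare
alleles; the package warns below 100 sequences per sex or pooled
MAF < 0.05, mirroring the default MAF filter. Guidance: relax the filter
to 0.01 only for very large samples.

Case-control log-odds ratios (sex as the binary state) use the Woolf
standard error `sqrt(1/a+1/b+1/c+1/d)` with Haldane-Anscombe `+0.5`
correction on zero cells (flagged). On large-sample null simulations the
`|L/SE|` and `2 n_H F̂_ST` tests rank loci near-identically (rank
correlation > 0.99, tested), so the odds-ratio route matters mainly when
structure covariates are needed — which is outside this package's scope.

## Power and minimum detectable selection

`fst_power` evaluates `P(F̂_ST > q_{1−α}^null)` via the noncentral
survival function at the scaled threshold. `s_min` solves
`E[statistic | s] = q_{1−α}^null` by bisection on `s ∈ (0, 1]` (tolerance
1e-6), using `E[F̂_ST] = (1+λ)/c` for F̂_ST, `1/(2n) + F_ST(s)` for F̂_IS,
and `|E L|/SE = z_{1−α/2}` for the log-odds metric. Designs where even
`s = 1` cannot reach the threshold return an "undetectable" sentinel
rather than a number.

Mapping a scalar per-sex cost `s` onto SA parameters is genuinely open;
two modes are provided. The default, `symmetric-cost`, sets `s_f = +s`,
`s_m = −s/(1+s)` so the *relative* fitness cost of carrying the
disfavoured homozygote is exactly `s` in each sex; `plain` sets
`s_m = −s`. The modes bracket the plausible readings and differ only at
second order in `s`.

## Synthetic data

The panel generator represents the canonical simulation design: neutral
loci with frequencies uniform on `[maf_min, 1−maf_min]` (a truncated 1/x
neutral-SFS mode is available for metrics whose nulls depend on the MAF
spectrum), SA loci at intermediate frequency `p = 1/2` with additive
effects and exponentially distributed selection coefficients
(`s_avg = 0.03` by default), frequency divergence applied in one
generation *before* sequences are sampled. Loci in perfect LD with an SA
target are statistically identical to the target, so hitchhikers need no
explicit linkage machinery. The MAF filter acts on the *sampled* pooled
frequency — what an empiricist observes.

What the generator does **not** emulate: genetic drift and coalescent
ancestry (no shared genealogies, hence no LD between loci), genotyping
error, read-mapping artifacts (sex-chromosome paralogs, coverage bias),
and multi-generation selection equilibria. Passing tests therefore
demonstrate the statistical machinery under its stated assumptions, not
robustness to data-quality pathologies; the structure-scenario generator
(Balding-Nichols deme frequencies with sex-uneven sampling proportions)
covers the one artifact class that is purely statistical.

VCF fixtures are minimal VCF 4.2 text files (single-base REF/ALT, GT-only
FORMAT) with a companion `sample<TAB>F|M` map; genotypes are two Bernoulli
gene copies from the sex's frequency, with optional independent missing
masking. The loader recovers the generator's complete-case counts exactly
(round-trip tested).

## Genome scan

Sites are filtered in a fixed, logged order: biallelic SNP → missingness
(default ≤ 50%) → optional BED exclusion regions (0-based half-open;
intended for known sex-linked or paralogous regions) → pooled MAF
(default ≥ 0.05; monomorphic sites logged separately) → optional exact
Hardy-Weinberg test. The HWE filter is **off** by default: sex-differential
selection itself produces heterozygote excess, so aggressive HWE filtering
can delete exactly the signal being sought. Every input site is either
retained or appears exactly once in the filter log (conservation is
tested). Multiallelic sites are skipped, not decomposed: the theory is
biallelic.

Each SNP gets `F̂_ST`, a p-value from its own missingness-aware `n_H`, and
its null-CDF value `χ²_1(2 n_H F̂_ST)`. Quantile binning uses that
null-CDF value, which makes "equal-probability quantiles of the
theoretical null" exact under heterogeneous per-site sample sizes.

Permutation nulls shuffle sex labels over *individuals* (both gene copies
and the missingness pattern travel together), preserving the sex ratio;
per-replicate bin counts, tail counts and mean `F̂_ST` are retained.
Replicate seeds derive from the master seed. Small samples make `F̂_ST`
discrete — the observed and permuted distributions share the discreteness
while the continuous theoretical null does not, so low quantile bins can
be systematically empty at small `n_H`. Observed-vs-permuted comparisons
are therefore the primary per-bin diagnostic, with theoretical comparisons
most meaningful in the tails.

Tail tests default to a 1-df goodness-of-fit of the observed above/below
split against the analytic tail mass `αN` (the null is analytic, so no
permutation noise enters); an observed-vs-permuted 2×2 contingency mode is
available. The mean-inflation test uses the `+1` smoothed permutation
p-value `(1 + #{perm ≥ obs})/(1 + B)`, never zero. Tail enrichment is
converted to error rates by `FDR = α/f_obs` and true-positive fraction
`1 − α/f_obs`; deflated tails clamp to FDR 1 with a flag.

## Numerical and interface choices

* `p̂` in the estimator denominator is the **unweighted** mean
  `(p̂_f+p̂_m)/2` even for unbalanced designs (documented divergence risk
  when `n_f` and `n_m` are very different); the pooled-MAF *filter* uses
  the overall allele-count frequency, matching common VCF tooling.
* F̂_IS sign convention: heterozygote excess positive — the reverse of
  Wright's inbreeding coefficient convention.
* Pooled-monomorphic loci yield NaN/errors rather than silent zeros.
* First-order breeding frequencies are clamped to `[0,1]` with a warning
  when strong selection makes the expansion overshoot.
* Only Nei's estimator is implemented; Hudson or Weir-Cockerham
  alternatives would slot in behind `fst_from_counts`.
* Test problem sizes: calibration tests use 10⁵ loci/replicates; the
  end-to-end fixtures use 2×10⁴ SNPs at 50 individuals/sex (null) and
  10,500 SNPs at 200 individuals/sex with fixed `s = 0.6` (positive
  control, chosen for high per-locus power so truth-label accounting has
  small binomial error).

## Known limitations

Single-generation theory only: no equilibria under recurrent selection, no
drift, no X/Z-linked or haploid-phase inheritance. No kinship/PC-corrected
association testing, no SNP-heritability estimation, and no concatenated
or gene-wide F_ST nulls (linkage invalidates the per-SNP null there). The
permutation machinery assumes exchangeable individuals under the null —
cryptic relatedness or structure violates this and is exactly the artifact
the structure simulator demonstrates.
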