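"""Sampling distributions, p-values, power, and detectability thresholds.

Under the null of identical allele frequencies in the two sexes, the
between-sex estimator satisfies F̂_ST ≈ X0 / (2 n_H) with X0 ~ χ²(1) and
n_H the harmonic mean of the per-sex gene-sequence sample sizes. Under
fixed sex-specific frequencies (p_f, p_m) the scaled statistic

    c · F̂_ST ~ noncentral χ²(1, λ),
    λ = (p_f - p_m)² / (p_f(1-p_f)/n_f + p_m(1-p_m)/n_m),
    c = 4 n_f n_m p̄(1-p̄) / (n_m p_f(1-p_f) + n_f p_m(1-p_m)).

Offspring-cohort F̂_IS is approximately Normal(1/(2n) + signal, 1/n) where
the signal term equals the parental between-sex F_ST. These distributions
drive the p-values, the power calculator, and the minimum-detectable-
selection (s_min) solver below.

The χ²(1) approximation degrades when per-sex sample sizes are small or the
minor allele is rare; a warning is emitted below n = 100 sequences per sex
or pooled MAF < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2, norm

from .estimators import FstEstimate, OddsRatioStat, harmonic_mean_n
from .model import SelectionParams, SexFreqs, breeding_freqs_approx, breeding_freqs_exact, population_fst

__all__ = [
    "FstNullSpec",
    "FstAltSpec",
    "FisNullSpec",
    "PowerResult",
    "SminResult",
    "fst_null_quantile",
    "fst_null_pvalue",
    "noncentrality",
    "fst_alt_spec",
    "fst_power",
    "fis_null_moments",
    "fis_alt_mean",
    "fis_pvalue",
    "s_min",
    "lor_null_pvalue",
    "sa_selection_params",
]

_SMALL_N_WARN = 100
_LOW_MAF_WARN = 0.05


@dataclass(frozen=True)
class FstNullSpec:
    """Null sampling model for F̂_ST: X0/(2 n_H) with X0 ~ χ²(1)."""

    n_H: float

    def __post_init__(self) -> None:
        if self.n_H <= 0:
            raise ValueError("harmonic mean sample size must be positive")


@dataclass(frozen=True)
class FstAltSpec:
    """Alternative sampling model: scale · F̂_ST ~ noncentral χ²(1, lambda)."""

    p_f: float
    p_m: float
    n_f: float
    n_m: float
    lam: float
    scale: float


@dataclass(frozen=True)
class FisNullSpec:
    """Null sampling model for F̂_IS: Normal(1/(2n), 1/n) for cohort size n."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")


@dataclass(frozen=True)
class PowerResult:
    alpha: float
    power: float
    threshold: float


@dataclass(frozen=True)
class SminResult:
    s_min: float
    alpha: float
    metric: str
    detectable: bool = True


def fst_null_quantile(spec: FstNullSpec | float, q: float) -> float:
    """Quantile of the null F̂_ST distribution: χ²(1) quantile / (2 n_H).

    At q = 0.99 the product with n_H is ≈ 3.32, i.e. roughly 1% of null
    loci exceed 3.32 / n_H.
    """
    n_h = spec.n_H if isinstance(spec, FstNullSpec) else float(spec)
    if n_h <= 0:
        raise ValueError("n_H must be positive")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile probability must be in (0, 1); got {q}")
    return chi2.ppf(q, df=1) / (2.0 * n_h)


def fst_null_pvalue(f_hat: FstEstimate | float, n_H: float | None = None):
    """Upper-tail null p-value: survival of χ²(1) at 2 n_H F̂_ST.

    Accepts an :class:`~sexscan.estimators.FstEstimate` or a raw value with
    an explicit ``n_H``; array input is supported in the latter form.
    """
    if isinstance(f_hat, FstEstimate):
        value, n_h = f_hat.value, f_hat.n_H
    else:
        if n_H is None:
            raise ValueError("n_H required when passing a raw F̂_ST value")
        value, n_h = f_hat, n_H
    return chi2.sf(2.0 * np.asarray(n_h, dtype=float) * np.asarray(value, dtype=float), df=1)


def noncentrality(p_f: float, p_m: float, n_f: float, n_m: float) -> tuple[float, float]:
    """Noncentrality λ and scale c of the alternative distribution of F̂_ST.

    Under the null (p_f = p_m, n_f = n_m) the scale reduces to 2 n_H,
    recovering the central χ²(1)/(2 n_H) null.
    """
    vf = p_f * (1.0 - p_f)
    vm = p_m * (1.0 - p_m)
    denom = n_m * vf + n_f * vm
    if denom <= 0:
        raise ValueError("both sexes monomorphic: alternative distribution undefined")
    lam = (p_f - p_m) ** 2 / (vf / n_f + vm / n_m)
    pbar = 0.5 * (p_f + p_m)
    scale = 4.0 * n_f * n_m * pbar * (1.0 - pbar) / denom
    return lam, scale


def fst_alt_spec(p_f: float, p_m: float, n_f: float, n_m: float) -> FstAltSpec:
    """Bundle :func:`noncentrality` into an :class:`FstAltSpec`, with
    approximation-quality warnings for small samples or rare alleles."""
    pbar = 0.5 * (p_f + p_m)
    maf = min(pbar, 1.0 - pbar)
    if min(n_f, n_m) < _SMALL_N_WARN or maf < _LOW_MAF_WARN:
        warnings.warn(
            "chi-squared approximation may be poor: fewer than "
            f"{_SMALL_N_WARN} sequences per sex or pooled MAF below {_LOW_MAF_WARN}",
            RuntimeWarning,
            stacklevel=2,
        )
    lam, scale = noncentrality(p_f, p_m, n_f, n_m)
    return FstAltSpec(p_f=p_f, p_m=p_m, n_f=n_f, n_m=n_m, lam=lam, scale=scale)


def _breeding(p: float, sel: SelectionParams, exact: bool) -> SexFreqs:
    return breeding_freqs_exact(p, sel) if exact else breeding_freqs_approx(p, sel)


def fst_power(
    sel: SelectionParams,
    p: float,
    n_f: float,
    n_m: float,
    alpha: float = 0.05,
    exact: bool = True,
) -> PowerResult:
    """Probability that F̂_ST at a selected locus exceeds the null tail.

    Computes the breeding-adult frequencies from the birth frequency ``p``
    (exact recursion by default; set ``exact=False`` for the first-order
    formula), then evaluates the noncentral χ²(1, λ) survival function at
    the scaled null threshold.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    freqs = _breeding(p, sel, exact)
    n_h = harmonic_mean_n(n_f, n_m)
    threshold = fst_null_quantile(FstNullSpec(n_H=n_h), 1.0 - alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spec = fst_alt_spec(freqs.p_f, freqs.p_m, n_f, n_m)
    power = float(ncx2.sf(spec.scale * threshold, df=1, nc=spec.lam))
    return PowerResult(alpha=alpha, power=power, threshold=threshold)


def fis_null_moments(spec: FisNullSpec) -> tuple[float, float]:
    """Mean 1/(2n) and variance 1/n of null offspring-cohort F̂_IS."""
    return 1.0 / (2.0 * spec.n), 1.0 / spec.n


def fis_alt_mean(freqs: SexFreqs, n: int) -> float:
    """E[F̂_IS] = 1/(2n) + (p_f - p_m)² / (4 p̄ (1 - p̄)); variance stays 1/n."""
    return 1.0 / (2.0 * n) + population_fst(freqs)


def fis_pvalue(fis, spec: FisNullSpec):
    """One-sided upper-tail p-value for F̂_IS under Normal(1/(2n), 1/n).

    One-sided because sex-differential parental frequencies can only raise
    the expected offspring heterozygosity (the signal term is a square).
    """
    if spec.n < 30:
        warnings.warn(
            "normal approximation for F̂_IS is unreliable below n = 30",
            RuntimeWarning,
            stacklevel=2,
        )
    mean, var = fis_null_moments(spec)
    return norm.sf(np.asarray(fis, dtype=float), loc=mean, scale=np.sqrt(var))


def lor_null_pvalue(stat: OddsRatioStat | float):
    """Two-sided p-value for the log-odds z = L/SE under Normal(0, 1)."""
    z = stat.z if isinstance(stat, OddsRatioStat) else stat
    return 2.0 * norm.sf(np.abs(np.asarray(z, dtype=float)))


def sa_selection_params(
    s: float, h: float = 0.5, mode: str = "symmetric-cost"
) -> SelectionParams:
    """Map a per-sex selection cost s onto a sexually antagonistic parameter pair.

    ``symmetric-cost`` (default): s_f = +s, s_m = -s/(1+s), so the relative
    fitness cost of the disfavoured homozygote is exactly s in both sexes.
    ``plain``: s_f = +s, s_m = -s (equal raw coefficients). The same
    dominance coefficient h applies in both sexes.
    """
    if s < 0:
        raise ValueError("selection cost s must be nonnegative")
    if mode == "symmetric-cost":
        s_m = -s / (1.0 + s)
    elif mode == "plain":
        s_m = -s
    else:
        raise ValueError(f"unknown SA parameterization mode {mode!r}")
    return SelectionParams(s_f=s, s_m=s_m, h_f=h, h_m=h)


def _expected_fst_hat(s: float, p: float, h: float, n_f: float, n_m: float,
                      mode: str, exact: bool) -> float:
    sel = sa_selection_params(s, h=h, mode=mode)
    freqs = _breeding(p, sel, exact)
    lam, scale = noncentrality(freqs.p_f, freqs.p_m, n_f, n_m)
    return (1.0 + lam) / scale


def s_min(
    n_f: float,
    n_m: float | None = None,
    alpha: float = 0.05,
    metric: str = "fst",
    p: float = 0.5,
    h: float = 0.5,
    mode: str = "symmetric-cost",
    exact: bool = True,
    tol: float = 1e-6,
) -> SminResult:
    """Minimum per-sex SA selection cost detectable at tail probability alpha.

    Solves E[statistic | s] = null (1 - alpha) quantile over s ∈ (0, 1] by
    bisection. For F̂_ST the expectation is (1 + λ(s)) / scale(s) and n_f,
    n_m are gene-sequence counts; for F̂_IS the expectation is
    1/(2n) + F_ST(s) and ``n_f`` is the offspring cohort size n; for the
    log-odds metric the criterion is |E z(s)| = z_{1-alpha/2}. If even
    s = 1 cannot reach the threshold, the design is flagged undetectable
    (s_min = NaN).
    """
    metric = metric.lower()
    if metric not in {"fst", "fis", "lor"}:
        raise ValueError("metric must be one of 'fst', 'fis', 'lor'")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    if metric == "fst":
        if n_m is None:
            n_m = n_f
        n_h = harmonic_mean_n(n_f, n_m)
        target = fst_null_quantile(FstNullSpec(n_H=n_h), 1.0 - alpha)

        def gap(s: float) -> float:
            return _expected_fst_hat(s, p, h, n_f, n_m, mode, exact) - target

    elif metric == "fis":
        n = int(n_f)
        z_crit = norm.ppf(1.0 - alpha)
        # E[F̂_IS] - null quantile: signal(s) must reach z_crit / sqrt(n)
        target = z_crit / np.sqrt(n)

        def gap(s: float) -> float:
            freqs = _breeding(p, sa_selection_params(s, h=h, mode=mode), exact)
            return population_fst(freqs) - target

    else:  # lor
        if n_m is None:
            n_m = n_f
        z_crit = norm.ppf(1.0 - alpha / 2.0)

        def gap(s: float) -> float:
            freqs = _breeding(p, sa_selection_params(s, h=h, mode=mode), exact)
            pf, pm = freqs.p_f, freqs.p_m
            if min(pf, pm) <= 0 or max(pf, pm) >= 1:
                return np.inf
            L = np.log((pm / (1.0 - pm)) / (pf / (1.0 - pf)))
            se = np.sqrt(
                1.0 / (n_m * pm) + 1.0 / (n_m * (1.0 - pm))
                + 1.0 / (n_f * pf) + 1.0 / (n_f * (1.0 - pf))
            )
            return abs(L) / se - z_crit

    lo, hi = 1e-6, 1.0
    if gap(hi) < 0:
        return SminResult(s_min=float("nan"), alpha=alpha, metric=metric, detectable=False)
    if gap(lo) >= 0:
        return SminResult(s_min=lo, alpha=alpha, metric=metric)
    root = brentq(gap, lo, hi, xtol=tol)
    return SminResult(s_min=float(root), alpha=alpha, metric=metric)
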