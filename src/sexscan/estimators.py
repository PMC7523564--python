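"""Sample statistics for sex-differential selection scans.

Estimators computed from sequenced/genotyped samples: Nei's between-sex
F̂_ST from per-sex allele counts, F̂_IS from offspring genotype counts, the
case-control log-odds ratio with Woolf standard error, the raw absolute
frequency difference, the sex-stratified GWAS t-statistic, and the 45°
rotation of (female, male) fitness onto sexually antagonistic / sexually
concordant axes.

Sign conventions
----------------
* F̂_IS follows the offspring-heterozygosity convention used throughout this
  package: heterozygote EXCESS is positive (the reverse of Wright's usual
  inbreeding sign).
* The log-odds ratio is oriented male-vs-female: L > 0 means the focal
  allele is more frequent in males.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MonomorphicLocusError

__all__ = [
    "AlleleCountsBySex",
    "GenotypeSample",
    "FstEstimate",
    "OddsRatioStat",
    "SexStratifiedEffect",
    "fst_nei",
    "fst_from_counts",
    "harmonic_mean_n",
    "fis_hat",
    "abs_freq_diff",
    "log_odds_ratio",
    "sex_diff_t",
    "rotate_fitness",
]


@dataclass(frozen=True)
class AlleleCountsBySex:
    """Focal-allele and total gene-sequence counts per sex at one locus.

    For diploid individuals n_j is twice the number of individuals of sex j
    with a non-missing genotype at the locus.
    """

    k_f: int
    n_f: int
    k_m: int
    n_m: int

    def __post_init__(self) -> None:
        if self.n_f < 1 or self.n_m < 1:
            raise ValueError("need at least one gene sequence per sex")
        if not (0 <= self.k_f <= self.n_f and 0 <= self.k_m <= self.n_m):
            raise ValueError("allele counts must satisfy 0 <= k <= n per sex")

    @property
    def p_f(self) -> float:
        return self.k_f / self.n_f

    @property
    def p_m(self) -> float:
        return self.k_m / self.n_m

    @property
    def p_pooled(self) -> float:
        """Unweighted mean of the per-sex sample frequencies, (p̂_f + p̂_m)/2."""
        return 0.5 * (self.p_f + self.p_m)


@dataclass(frozen=True)
class GenotypeSample:
    """Genotype counts (AA, Aa, aa) for an offspring cohort at one locus."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.n < 1:
            raise ValueError("cohort must contain at least one individual")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa

    @property
    def p_hat(self) -> float:
        return (2 * self.n_AA + self.n_Aa) / (2 * self.n)


@dataclass(frozen=True)
class FstEstimate:
    value: float
    n_H: float
    p_hat_f: float
    p_hat_m: float
    p_hat: float


@dataclass(frozen=True)
class OddsRatioStat:
    L: float
    SE: float
    z: float
    continuity_corrected: bool = False


@dataclass(frozen=True)
class SexStratifiedEffect:
    """Per-sex GWAS effect sizes, standard errors, and the genome-wide
    between-sex rank correlation used in the sex-difference t-statistic."""

    beta_f: float
    beta_m: float
    se_f: float
    se_m: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.se_f <= 0 or self.se_m <= 0:
            raise ValueError("standard errors must be positive")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must not exceed 1")


def harmonic_mean_n(n_f: float, n_m: float) -> float:
    """Harmonic mean sample size n_H = 2 (1/n_f + 1/n_m)^-1."""
    if n_f <= 0 or n_m <= 0:
        raise ValueError("sample sizes must be positive")
    return 2.0 / (1.0 / n_f + 1.0 / n_m)


def fst_from_counts(k_f, n_f, k_m, n_m):
    """Vectorised Nei between-sex F̂_ST; returns (fst, n_H) arrays.

    Pooled-monomorphic loci (p̂ in {0, 1}) yield NaN — the statistic is
    undefined there and such sites are excluded from scans.
    """
    k_f = np.asarray(k_f, dtype=float)
    n_f = np.asarray(n_f, dtype=float)
    k_m = np.asarray(k_m, dtype=float)
    n_m = np.asarray(n_m, dtype=float)
    p_f = k_f / n_f
    p_m = k_m / n_m
    pbar = 0.5 * (p_f + p_m)
    denom = 4.0 * pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom > 0, (p_f - p_m) ** 2 / denom, np.nan)
    n_h = 2.0 / (1.0 / n_f + 1.0 / n_m)
    return fst, n_h


def fst_nei(counts: AlleleCountsBySex) -> FstEstimate:
    """Nei's between-sex F̂_ST = (p̂_f - p̂_m)^2 / (4 p̂ (1 - p̂)).

    The denominator uses the unweighted mean p̂ = (p̂_f + p̂_m)/2 even for
    unbalanced designs. Invariant under relabelling the focal allele and
    under swapping the sexes.
    """
    p_f, p_m = counts.p_f, counts.p_m
    pbar = counts.p_pooled
    if pbar <= 0.0 or pbar >= 1.0:
        raise MonomorphicLocusError(
            "F̂_ST undefined: locus monomorphic in the pooled sample"
        )
    value = (p_f - p_m) ** 2 / (4.0 * pbar * (1.0 - pbar))
    return FstEstimate(
        value=value,
        n_H=harmonic_mean_n(counts.n_f, counts.n_m),
        p_hat_f=p_f,
        p_hat_m=p_m,
        p_hat=pbar,
    )


def fis_hat(sample: GenotypeSample) -> float:
    """Offspring-cohort F̂_IS = (n_Aa / n) / (2 p̂ (1 - p̂)) - 1.

    Positive values indicate heterozygote excess, the expected signature of
    sex-differential parental allele frequencies. Bounded below by -1.
    """
    p = sample.p_hat
    if p <= 0.0 or p >= 1.0:
        raise MonomorphicLocusError("F̂_IS undefined: sample monomorphic")
    het_obs = sample.n_Aa / sample.n
    return het_obs / (2.0 * p * (1.0 - p)) - 1.0


def abs_freq_diff(counts: AlleleCountsBySex) -> float:
    """Raw absolute frequency difference |p̂_f - p̂_m|.

    Retained for comparison only: unlike F̂_ST, its null distribution
    covaries strongly with minor-allele frequency, so genome-wide use
    requires MAF-matched simulated nulls.
    """
    return abs(counts.p_f - counts.p_m)


def log_odds_ratio(counts: AlleleCountsBySex) -> OddsRatioStat:
    """Sex-association log-odds ratio with Woolf (Wald) standard error.

    The 2x2 table is (focal, alternative allele) x (male, female) gene
    sequences. SE = sqrt(1/a + 1/b + 1/c + 1/d). Any zero cell triggers the
    Haldane-Anscombe continuity correction (+0.5 to every cell), flagged on
    the returned record.
    """
    a = counts.k_m
    b = counts.n_m - counts.k_m
    c = counts.k_f
    d = counts.n_f - counts.k_f
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    L = math.log((a / b) / (c / d))
    SE = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return OddsRatioStat(L=L, SE=SE, z=L / SE, continuity_corrected=corrected)


def sex_diff_t(eff: SexStratifiedEffect) -> float:
    """Sex-difference t = (β_M - β_F) / sqrt(SE_M^2 + SE_F^2 - 2 ρ SE_M SE_F).

    ρ is the between-sex rank correlation of effect sizes across genome-wide
    loci; under the null of no sex-specific effect, E[t] = 0 and t is
    referred to a standard normal.
    """
    var = eff.se_m**2 + eff.se_f**2 - 2.0 * eff.rho * eff.se_m * eff.se_f
    if var <= 0:
        raise ValueError(
            "degenerate variance: SE_M^2 + SE_F^2 - 2 rho SE_M SE_F must be positive"
        )
    return (eff.beta_m - eff.beta_f) / math.sqrt(var)


def rotate_fitness(w_f, w_m):
    """45° rotation of (female, male) fitness onto (SA, SC) axes.

    SA = (w_f - w_m)/sqrt(2) captures sexually antagonistic variation,
    SC = (w_f + w_m)/sqrt(2) sexually concordant variation. The rotation is
    orthogonal, so SA^2 + SC^2 = w_f^2 + w_m^2. Inputs are used as given;
    standardise per sex beforehand if scales differ.
    """
    w_f = np.asarray(w_f, dtype=float)
    w_m = np.asarray(w_m, dtype=float)
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    return (w_f - w_m) * inv_sqrt2, (w_f + w_m) * inv_sqrt2
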