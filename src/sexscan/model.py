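"""Deterministic population-genetic expectations for sex-specific processes.

This module holds the single-generation theory that the rest of the package
builds on: allele frequencies among breeding females and males after one
episode of sex-specific viability selection (exact recursion and its
first-order weak-selection expansion), the analogous expectations under
sex-biased migration, offspring genotype frequencies under random mating,
and the population-level fixation indices F_ST (between sexes) and F_IS
(offspring heterozygote excess).

All functions are pure and operate on scalars; vectorised counterparts used
by the simulator live in the private ``_breeding_*`` helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionParams",
    "MigrationParams",
    "SexFreqs",
    "GenotypeFreqs",
    "MonomorphicLocusError",
    "breeding_freqs_approx",
    "breeding_freqs_exact",
    "migration_freqs",
    "offspring_genotype_freqs",
    "population_fst",
    "population_fis",
]


class MonomorphicLocusError(ValueError):
    """Raised when a fixation index is requested for a fixed locus (p̄ ∈ {0, 1})."""


@dataclass(frozen=True)
class SelectionParams:
    """Sex-specific selection and dominance coefficients for a biallelic locus.

    Relative fitnesses are 1 + s_j, 1 + s_j*h_j, 1 for the AA, Aa and aa
    genotypes in sex j. A sexually antagonistic locus has s_f and s_m of
    opposite sign.
    """

    s_f: float = 0.0
    s_m: float = 0.0
    h_f: float = 0.5
    h_m: float = 0.5

    def __post_init__(self) -> None:
        if self.s_f <= -1.0 or self.s_m <= -1.0:
            raise ValueError(
                "selection coefficients must exceed -1 (homozygote fitness 1+s > 0); "
                f"got s_f={self.s_f}, s_m={self.s_m}"
            )
        if not (np.isfinite(self.h_f) and np.isfinite(self.h_m)):
            raise ValueError("dominance coefficients must be finite")


@dataclass(frozen=True)
class MigrationParams:
    """Sex-specific migrant proportions and migrant-pool allele frequency.

    m_f and m_m are the proportions of breeding females and males that are
    migrants; p_tilde is the focal-allele frequency among migrants.
    """

    m_f: float
    m_m: float
    p_tilde: float

    def __post_init__(self) -> None:
        for name in ("m_f", "m_m", "p_tilde"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")


@dataclass(frozen=True)
class SexFreqs:
    """Focal-allele frequencies among breeding females (p_f) and males (p_m)."""

    p_f: float
    p_m: float

    def __post_init__(self) -> None:
        for name in ("p_f", "p_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")

    @property
    def p_bar(self) -> float:
        """Mean breeding-adult frequency (p_f + p_m) / 2 — also the offspring frequency."""
        return 0.5 * (self.p_f + self.p_m)


@dataclass(frozen=True)
class GenotypeFreqs:
    """Population frequencies of the three diploid genotypes at a biallelic locus."""

    f_AA: float
    f_Aa: float
    f_aa: float

    def __post_init__(self) -> None:
        if min(self.f_AA, self.f_Aa, self.f_aa) < 0:
            raise ValueError("genotype frequencies must be nonnegative")
        total = self.f_AA + self.f_Aa + self.f_aa
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies must sum to 1; got {total!r}")


def _check_p(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1]; got {p}")


def _breeding_approx(p, s, h):
    """First-order (weak-selection) change in allele frequency, vectorised.

    p_j = p + s_j p (1-p) [h_j + p (1 - 2 h_j)], dropping O(s^2) terms.
    """
    p = np.asarray(p, dtype=float)
    return p + s * p * (1.0 - p) * (h + p * (1.0 - 2.0 * h))


def _breeding_exact(p, s, h):
    """Exact one-generation viability-selection recursion, vectorised.

    Assumes Hardy-Weinberg genotype proportions at birth; relative fitnesses
    1+s, 1+sh, 1 for AA, Aa, aa.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    num = p * p * (1.0 + s) + p * q * (1.0 + s * h)
    wbar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + s * h) + q * q
    if np.any(wbar <= 0):
        raise ValueError("mean fitness is nonpositive; selection parameters invalid")
    return num / wbar


def breeding_freqs_approx(p: float, sel: SelectionParams) -> SexFreqs:
    """Breeding-adult allele frequencies by the first-order weak-selection formula.

    Accurate to O(s^2); results are clamped to [0, 1] with a warning when the
    expansion overshoots (which can happen for large ``s``).
    """
    _check_p(p)
    p_f = float(_breeding_approx(p, sel.s_f, sel.h_f))
    p_m = float(_breeding_approx(p, sel.s_m, sel.h_m))
    if not (0.0 <= p_f <= 1.0 and 0.0 <= p_m <= 1.0):
        warnings.warn(
            "first-order breeding frequency outside [0, 1]; clamping "
            "(selection too strong for the weak-selection expansion)",
            RuntimeWarning,
            stacklevel=2,
        )
        p_f = float(np.clip(p_f, 0.0, 1.0))
        p_m = float(np.clip(p_m, 0.0, 1.0))
    return SexFreqs(p_f=p_f, p_m=p_m)


def breeding_freqs_exact(p: float, sel: SelectionParams) -> SexFreqs:
    """Breeding-adult allele frequencies by the exact viability-selection recursion.

    p_j' = [p^2 (1+s_j) + p(1-p)(1+s_j h_j)] / w̄_j with Hardy-Weinberg
    proportions at birth. Serves as the reference for the first-order
    approximation and stays valid for arbitrarily strong selection.
    """
    _check_p(p)
    return SexFreqs(
        p_f=float(_breeding_exact(p, sel.s_f, sel.h_f)),
        p_m=float(_breeding_exact(p, sel.s_m, sel.h_m)),
    )


def migration_freqs(p: float, mig: MigrationParams) -> SexFreqs:
    """Breeding-adult allele frequencies under sex-biased migration.

    p_j = (1 - m_j) p + m_j p̃, which implies the exact identity
    p_f - p_m = (m_f - m_m)(p̃ - p): a between-sex frequency difference
    requires both sex-biased migration and migrant/resident differentiation.
    """
    _check_p(p)
    return SexFreqs(
        p_f=(1.0 - mig.m_f) * p + mig.m_f * mig.p_tilde,
        p_m=(1.0 - mig.m_m) * p + mig.m_m * mig.p_tilde,
    )


def offspring_genotype_freqs(freqs: SexFreqs) -> GenotypeFreqs:
    """Offspring genotype frequencies under random mating of the breeding adults.

    P_AA = p_f p_m, P_Aa = p_f(1-p_m) + p_m(1-p_f), P_aa = (1-p_f)(1-p_m).
    Sex-differential parental frequencies elevate heterozygosity above the
    Hardy-Weinberg expectation at the offspring frequency p̄.
    """
    pf, pm = freqs.p_f, freqs.p_m
    return GenotypeFreqs(
        f_AA=pf * pm,
        f_Aa=pf * (1.0 - pm) + pm * (1.0 - pf),
        f_aa=(1.0 - pf) * (1.0 - pm),
    )


def population_fst(freqs: SexFreqs) -> float:
    """Population between-sex F_ST = (p_f - p_m)^2 / (4 p̄ (1 - p̄)).

    Zero iff the sexes share an allele frequency; undefined at a fixed locus.
    """
    pbar = freqs.p_bar
    if pbar <= 0.0 or pbar >= 1.0:
        raise MonomorphicLocusError(
            f"between-sex F_ST undefined for monomorphic locus (p̄={pbar})"
        )
    return (freqs.p_f - freqs.p_m) ** 2 / (4.0 * pbar * (1.0 - pbar))


def population_fis(freqs: SexFreqs) -> float:
    """Population offspring F_IS = P_Aa / (2 p̄ (1 - p̄)) - 1.

    Sign convention: heterozygote *excess* is positive. Algebraically equal
    to :func:`population_fst` of the parental generation, which is the basis
    of the heterozygosity route to detecting sex-differential selection.
    """
    pbar = freqs.p_bar
    if pbar <= 0.0 or pbar >= 1.0:
        raise MonomorphicLocusError(
            f"F_IS undefined for monomorphic locus (p̄={pbar})"
        )
    het = offspring_genotype_freqs(freqs).f_Aa
    return het / (2.0 * pbar * (1.0 - pbar)) - 1.0
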