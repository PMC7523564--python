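"""Seeded synthetic-data generation for sex-differential selection studies.

Generates locus panels mixing neutrally evolving loci with loci responding
to sexually antagonistic (SA) selection, binomially samples gene sequences
per sex, draws multinomial offspring cohorts under random mating, builds
hidden-population-structure artifact scenarios, and writes minimal VCF
fixtures (plus sample→sex maps) for end-to-end pipeline tests.

The default panel emulates the canonical study design: neutral loci with a
uniform frequency spectrum above the MAF filter, SA-responding loci at
intermediate frequency (p = 1/2) with additive effects (h = 1/2) and
selection coefficients drawn from an exponential distribution with mean
s_avg = 0.03, frequency divergence applied before gene sequences are
sampled. Loci in perfect linkage disequilibrium with an SA target behave
identically to the target itself, so hitchhikers are represented by the
same mechanism rather than by explicit multi-locus LD.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import GenotypeSample, fst_from_counts
from .model import SexFreqs, _breeding_exact, offspring_genotype_freqs
from .null_models import fst_null_pvalue, sa_selection_params

__all__ = [
    "PanelConfig",
    "StructureScenario",
    "simulate_fst_panel",
    "simulate_offspring_cohort",
    "simulate_structure_artifact",
    "write_vcf_fixture",
]


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a simulated locus panel.

    Parameters
    ----------
    n_neutral, n_sa
        Numbers of neutral and SA-responding loci.
    n_f, n_m
        Gene sequences sampled per sex (2x individuals for diploids).
    p_init
        Initial-frequency model for neutral loci: ``"uniform"`` on
        [maf_min, 1 - maf_min], ``"fixed"`` at ``p_fixed``, or ``"sfs"``
        (neutral 1/x spectrum truncated at maf_min).
    p_fixed
        Frequency used by the ``"fixed"`` mode and for SA loci (the
        canonical design places SA loci at intermediate frequency 1/2).
    s_dist, s_avg
        Selection-coefficient model for SA loci: ``"exponential"`` with
        mean ``s_avg``, or ``"fixed"`` at ``s_avg``.
    h
        Dominance coefficient (both sexes); 1/2 = additive.
    sa_mode
        Mapping from the per-sex cost s to (s_f, s_m); see
        :func:`sexscan.null_models.sa_selection_params`.
    maf_min
        Pooled *sampled* minor-allele-frequency threshold below which a
        locus is flagged as not retained (what an empiricist would filter).
    seed
        Random seed; identical configs and seeds give identical tables.
    """

    n_neutral: int = 100_000
    n_sa: int = 1_000
    n_f: int = 200
    n_m: int = 200
    p_init: str = "uniform"
    p_fixed: float = 0.5
    s_dist: str = "exponential"
    s_avg: float = 0.03
    h: float = 0.5
    sa_mode: str = "symmetric-cost"
    maf_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neutral < 0 or self.n_sa < 0:
            raise ValueError("locus counts must be nonnegative")
        if self.n_f < 1 or self.n_m < 1:
            raise ValueError("need at least one sequence per sex")
        if self.p_init not in {"uniform", "fixed", "sfs"}:
            raise ValueError(f"unknown p_init mode {self.p_init!r}")
        if self.s_dist not in {"exponential", "fixed"}:
            raise ValueError(f"unknown s_dist mode {self.s_dist!r}")
        if self.s_avg <= 0:
            raise ValueError("s_avg must be positive")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


def _draw_neutral_freqs(config: PanelConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_min, 1.0 - config.maf_min
    if config.p_init == "fixed":
        return np.full(config.n_neutral, config.p_fixed)
    if config.p_init == "uniform":
        return rng.uniform(lo, hi, size=config.n_neutral)
    # neutral SFS: density proportional to 1/x on [lo, hi], folded symmetric
    # in expectation because the focal allele is an arbitrary label
    u = rng.uniform(size=config.n_neutral)
    p = lo * (hi / lo) ** u
    flip = rng.random(config.n_neutral) < 0.5
    return np.where(flip, 1.0 - p, p)


def simulate_fst_panel(config: PanelConfig) -> pd.DataFrame:
    """Simulate a panel of loci and the per-sex allele counts sampled from it.

    Neutral loci share a frequency between the sexes; SA loci diverge by one
    generation of sex-specific selection (exact viability recursion) before
    k_f ~ Binomial(n_f, p_f) and k_m ~ Binomial(n_m, p_m) gene sequences are
    drawn. Returns one row per locus with truth labels, true and sampled
    frequencies, F̂_ST, its theoretical null p-value, and a ``retained``
    flag implementing the pooled sampled-MAF filter.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_neutral + config.n_sa

    p = np.empty(n_total)
    s = np.zeros(n_total)
    p[: config.n_neutral] = _draw_neutral_freqs(config, rng)
    p[config.n_neutral:] = config.p_fixed

    if config.n_sa:
        if config.s_dist == "exponential":
            s_sa = rng.exponential(config.s_avg, size=config.n_sa)
        else:
            s_sa = np.full(config.n_sa, config.s_avg)
        s[config.n_neutral:] = s_sa

    p_f = p.copy()
    p_m = p.copy()
    if config.n_sa:
        sa = slice(config.n_neutral, n_total)
        # map per-sex cost -> (s_f, s_m) pairs, then apply the exact recursion
        s_f = np.empty(config.n_sa)
        s_m = np.empty(config.n_sa)
        for i, si in enumerate(s_sa):
            sel = sa_selection_params(float(si), h=config.h, mode=config.sa_mode)
            s_f[i], s_m[i] = sel.s_f, sel.s_m
        p_f[sa] = _breeding_exact(p[sa], s_f, config.h)
        p_m[sa] = _breeding_exact(p[sa], s_m, config.h)

    k_f = rng.binomial(config.n_f, p_f)
    k_m = rng.binomial(config.n_m, p_m)
    fst, n_h = fst_from_counts(k_f, config.n_f, k_m, config.n_m)
    pval = fst_null_pvalue(np.nan_to_num(fst), n_h)

    p_hat_f = k_f / config.n_f
    p_hat_m = k_m / config.n_m
    pooled = (k_f + k_m) / (config.n_f + config.n_m)
    maf_hat = np.minimum(pooled, 1.0 - pooled)
    retained = maf_hat >= max(config.maf_min, np.finfo(float).tiny)

    return pd.DataFrame(
        {
            "locus": np.arange(n_total),
            "truth": np.repeat(["neutral", "SA"], [config.n_neutral, config.n_sa]),
            "p": p,
            "s": s,
            "p_f": p_f,
            "p_m": p_m,
            "k_f": k_f,
            "n_f": config.n_f,
            "k_m": k_m,
            "n_m": config.n_m,
            "p_hat_f": p_hat_f,
            "p_hat_m": p_hat_m,
            "maf_hat": maf_hat,
            "fst": fst,
            "n_H": n_h,
            "p_value": np.where(np.isnan(fst), np.nan, pval),
            "retained": retained & ~np.isnan(fst),
        }
    )


def simulate_offspring_cohort(
    freqs: SexFreqs, n: int, seed: int | np.random.Generator = 0
) -> GenotypeSample:
    """Draw an offspring cohort of size n by random mating of (p_f, p_m) parents.

    Genotype counts are multinomial with probabilities (p_f p_m,
    p_f(1-p_m) + p_m(1-p_f), (1-p_f)(1-p_m)).
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = offspring_genotype_freqs(freqs)
    n_aa_het_bb = rng.multinomial(n, [g.f_AA, g.f_Aa, g.f_aa])
    return GenotypeSample(*(int(x) for x in n_aa_het_bb))


@dataclass(frozen=True)
class StructureScenario:
    """Hidden population structure with sex-uneven sampling across demes.

    Deme allele frequencies are drawn per locus around a shared ancestral
    frequency with between-deme differentiation ``fst_b`` (Balding-Nichols
    beta model). ``prop_f`` / ``prop_m`` give the fractions of female and
    male gene sequences drawn from each deme; unequal vectors mimic
    sex-uneven geographic sampling or sex-biased migration and inflate
    between-sex F̂_ST without any sex difference in selection.
    """

    prop_f: tuple[float, ...]
    prop_m: tuple[float, ...]
    fst_b: float = 0.05
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        if len(self.prop_f) != len(self.prop_m) or len(self.prop_f) < 1:
            raise ValueError("proportion vectors must be nonempty and equal length")
        for name in ("prop_f", "prop_m"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if not 0.0 < self.fst_b < 1.0:
            raise ValueError("between-deme F_ST must be in (0, 1)")


def simulate_structure_artifact(
    scn: StructureScenario, n_f: int, n_m: int, n_loci: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate neutral loci sampled through sex-uneven deme proportions.

    Per locus: ancestral p ~ Uniform(maf_min, 1 - maf_min); deme frequencies
    p_d ~ Beta with mean p and differentiation fst_b; each sex's sequences
    are allocated to demes multinomially by its proportion vector and
    sampled binomially within demes. With equal proportion vectors the
    output is null-calibrated; unequal vectors inflate mean F̂_ST above the
    null expectation 1/(2 n_H) despite every locus being neutral.
    """
    rng = np.random.default_rng(seed)
    n_demes = len(scn.prop_f)
    p0 = rng.uniform(scn.maf_min, 1.0 - scn.maf_min, size=n_loci)
    a = p0 * (1.0 - scn.fst_b) / scn.fst_b
    b = (1.0 - p0) * (1.0 - scn.fst_b) / scn.fst_b
    deme_p = rng.beta(a[:, None], b[:, None], size=(n_loci, n_demes))

    alloc_f = rng.multinomial(n_f, scn.prop_f, size=n_loci)
    alloc_m = rng.multinomial(n_m, scn.prop_m, size=n_loci)
    k_f = rng.binomial(alloc_f, deme_p).sum(axis=1)
    k_m = rng.binomial(alloc_m, deme_p).sum(axis=1)

    fst, n_h = fst_from_counts(k_f, n_f, k_m, n_m)
    pval = fst_null_pvalue(np.nan_to_num(fst), n_h)
    pooled = (k_f + k_m) / (n_f + n_m)
    maf_hat = np.minimum(pooled, 1.0 - pooled)
    return pd.DataFrame(
        {
            "locus": np.arange(n_loci),
            "truth": "neutral",
            "p": p0,
            "k_f": k_f,
            "n_f": n_f,
            "k_m": k_m,
            "n_m": n_m,
            "maf_hat": maf_hat,
            "fst": fst,
            "n_H": n_h,
            "p_value": np.where(np.isnan(fst), np.nan, pval),
            "retained": (maf_hat >= scn.maf_min) & ~np.isnan(fst),
        }
    )


_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
)


def write_vcf_fixture(
    panel: pd.DataFrame,
    individuals_per_sex: int,
    prefix: str | Path,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Write a minimal diploid VCF (plus sex map) realised from a locus panel.

    For each panel row, ``individuals_per_sex`` female and male diploid
    genotypes are drawn from that row's true sex-specific frequencies
    (``p_f``, ``p_m``); genotypes are independently masked as missing at
    ``missing_rate``. Writes ``<prefix>.vcf`` and ``<prefix>.sexmap.tsv``
    and returns the realised complete-case per-sex allele counts so that
    round-trip tests can compare against the loader's output exactly.
    """
    rng = np.random.default_rng(seed)
    prefix = Path(prefix)
    n_ind = individuals_per_sex
    n_loci = len(panel)

    p_f = panel["p_f"].to_numpy(dtype=float)
    p_m = panel["p_m"].to_numpy(dtype=float)
    # diploid dosage = sum of two Bernoulli gene copies from the sex's frequency
    dos_f = rng.binomial(2, p_f[:, None], size=(n_loci, n_ind)).astype(np.int8)
    dos_m = rng.binomial(2, p_m[:, None], size=(n_loci, n_ind)).astype(np.int8)
    dosage = np.concatenate([dos_f, dos_m], axis=1)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = 3  # index of "./." in _GT_STRINGS

    females = [f"F{i:04d}" for i in range(n_ind)]
    males = [f"M{i:04d}" for i in range(n_ind)]
    samples = females + males

    vcf_path = prefix.with_suffix(".vcf")
    sexmap_path = Path(str(prefix) + ".sexmap.tsv")
    pos = np.arange(1, n_loci + 1) * 100
    try:
        with open(vcf_path, "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            gt = _GT_STRINGS[dosage]
            for i in range(n_loci):
                fh.write(
                    f"1\t{pos[i]}\tL{i}\tA\tC\t.\tPASS\t.\tGT\t"
                    + "\t".join(gt[i])
                    + "\n"
                )
        with open(sexmap_path, "w") as fh:
            fh.write("# sample\tsex\n")
            for name in females:
                fh.write(f"{name}\tF\n")
            for name in males:
                fh.write(f"{name}\tM\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {prefix}: {exc}") from exc

    miss = dosage == 3
    dos0 = np.where(miss, 0, dosage)
    k_f = dos0[:, :n_ind].sum(axis=1)
    k_m = dos0[:, n_ind:].sum(axis=1)
    n_f = 2 * (~miss[:, :n_ind]).sum(axis=1)
    n_m = 2 * (~miss[:, n_ind:]).sum(axis=1)
    out = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "k_f": k_f,
            "n_f": n_f,
            "k_m": k_m,
            "n_m": n_m,
        }
    )
    if "truth" in panel.columns:
        out["truth"] = panel["truth"].to_numpy()
    return out
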