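"""Genome-scan pipeline for between-sex allele-frequency differentiation.

Ingests a VCF plus a sample→sex map, applies the standard site filters
(biallelic SNPs, missingness, optional BED exclusion regions, pooled MAF,
optional Hardy-Weinberg exact test), computes per-SNP between-sex F̂_ST
with theoretical χ²(1) p-values, builds sex-label permutation nulls,
summarises observed-vs-null occupancy over equal-probability quantile bins
of the theoretical null, runs tail and mean-inflation tests, and converts
tail enrichment into an implied false-discovery rate.

Binning is by each SNP's own null-CDF value (using that SNP's
missingness-aware n_H), so "quantiles of the theoretical null" remain
well-defined when per-site sample sizes vary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency

from .estimators import fst_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "GenotypeData",
    "PermutationResult",
    "TailTestResult",
    "MeanInflationResult",
    "FdrEstimate",
    "ScanResult",
    "load_genotypes",
    "compute_scan",
    "permute_scan",
    "quantile_enrichment",
    "tail_test",
    "mean_inflation_test",
    "estimate_fdr",
    "hwe_exact_pvalue",
    "run_scan",
    "write_report",
]


@dataclass(frozen=True)
class ScanConfig:
    """Filtering and testing configuration for a genome scan."""

    maf_min: float = 0.05
    max_missing: float = 0.5
    hwe_filter_alpha: float | None = None
    hwe_side: str = "both"
    exclude_bed: str | Path | None = None
    permutations: int = 1000
    quantile_bins: int = 100
    alphas: tuple[float, ...] = (0.05, 0.01)
    seed: int = 0
    ploidy: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if self.permutations < 1:
            raise ValueError("need at least one permutation")
        if self.quantile_bins < 2:
            raise ValueError("need at least two quantile bins")
        for a in self.alphas:
            if not 0.0 < a < 1.0:
                raise ValueError("tail alphas must be in (0, 1)")
        if self.hwe_side not in {"both", "excess", "deficit"}:
            raise ValueError("hwe_side must be 'both', 'excess' or 'deficit'")
        if self.ploidy not in {1, 2}:
            raise ValueError("ploidy must be 1 or 2")


@dataclass
class GenotypeData:
    """Filter-passing genotype matrix plus site metadata and the filter log.

    ``dosage`` holds the ALT-allele count per (site, individual); -1 marks a
    missing genotype. ``is_female`` aligns with the sample axis.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    is_female: np.ndarray
    ploidy: int
    n_input: int
    filter_counts: dict[str, int]
    filter_records: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def _read_sex_map(path: str | Path) -> dict[str, str]:
    sexes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>sex'")
            sample, sex = parts[0], parts[1].strip().upper()
            if sex in {"F", "FEMALE"}:
                sexes[sample] = "F"
            elif sex in {"M", "MALE"}:
                sexes[sample] = "M"
            else:
                raise ValueError(f"{path}:{lineno}: sex must be F or M, got {parts[1]!r}")
    return sexes


def _read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED file (0-based, half-open) into per-chromosome interval arrays."""
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.setdefault(chrom, []).append((int(start), int(end)))
    return {c: np.array(sorted(iv)) for c, iv in regions.items()}


def _in_regions(regions: dict[str, np.ndarray], chrom: str, pos_1based: int) -> bool:
    iv = regions.get(chrom)
    if iv is None or not len(iv):
        return False
    p = pos_1based - 1  # convert VCF 1-based to BED 0-based
    i = np.searchsorted(iv[:, 0], p, side="right") - 1
    return i >= 0 and p < iv[i, 1]


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int, side: str = "both") -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Enumerates all heterozygote counts compatible with the allele counts and
    sums hypergeometric-style probabilities. ``side`` selects two-sided
    ("both": tables no more probable than observed), heterozygote-excess, or
    heterozygote-deficit alternatives.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa  # minor-or-major: symmetric, use as given
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    het_obs = n_Aa
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalised log probabilities of each possible het count
    from scipy.special import gammaln

    n_aa_ = (rare - hets) // 2
    n_bb_ = n - n_aa_ - hets
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_aa_ + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb_ + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_idx = np.nonzero(hets == het_obs)[0]
    if not len(obs_idx):
        raise ValueError("heterozygote count incompatible with allele counts")
    i = obs_idx[0]
    if side == "both":
        return float(prob[prob <= prob[i] * (1 + 1e-12)].sum())
    if side == "excess":
        return float(prob[hets >= het_obs].sum())
    return float(prob[hets <= het_obs].sum())


def load_genotypes(
    vcf_path: str | Path,
    sexmap_path: str | Path,
    config: ScanConfig | None = None,
) -> GenotypeData:
    """Load a VCF and sex map into a filtered genotype matrix.

    Filters are applied per site in fixed order — biallelic SNP →
    missingness → exclusion regions → pooled MAF (monomorphic sites logged
    separately) → optional HWE exact test — and every excluded site is
    logged once with a reason code. Samples in the VCF but absent from the
    sex map raise an error (silent sex misassignment being the worst
    failure mode); sex-map entries absent from the VCF are ignored with a
    warning.
    """
    from cyvcf2 import VCF

    config = config or ScanConfig()
    sexes = _read_sex_map(sexmap_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)

    missing_from_map = [s for s in samples if s not in sexes]
    if missing_from_map:
        raise ValueError(
            f"samples in VCF but not in sex map: {missing_from_map[:5]}"
            f"{'...' if len(missing_from_map) > 5 else ''}"
        )
    unused = set(sexes) - set(samples)
    if unused:
        warnings.warn(
            f"{len(unused)} sex-map entries not present in VCF; ignoring",
            UserWarning,
            stacklevel=2,
        )
    is_female = np.array([sexes[s] == "F" for s in samples])
    if is_female.sum() < 2 or (~is_female).sum() < 2:
        raise ValueError("need at least 2 individuals of each sex")

    regions = _read_bed(config.exclude_bed) if config.exclude_bed else {}

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    counts: dict[str, int] = {}
    records: list[tuple[str, int, str]] = []
    n_input = 0
    n_samples = len(samples)

    def reject(chrom: str, pos: int, reason: str) -> None:
        counts[reason] = counts.get(reason, 0) + 1
        records.append((chrom, pos, reason))

    for var in vcf:
        n_input += 1
        chrom, pos = var.CHROM, var.POS
        if len(var.ALT) != 1 or not var.is_snp:
            reject(chrom, pos, "NOT_BIALLELIC_SNP")
            continue
        # gts012: 0/1/2 = dosage, 3 = missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        dos = np.where(gt == 3, np.int8(-1), gt)
        miss_frac = float((dos < 0).mean())
        if miss_frac > config.max_missing:
            reject(chrom, pos, "MISSING")
            continue
        if regions and _in_regions(regions, chrom, pos):
            reject(chrom, pos, "EXCLUDED_REGION")
            continue
        ok = dos >= 0
        n_alleles = config.ploidy * int(ok.sum())
        if n_alleles == 0:
            reject(chrom, pos, "MISSING")
            continue
        k = int(dos[ok].sum()) if config.ploidy == 2 else int((dos[ok] > 0).sum())
        p_pool = k / n_alleles
        if p_pool <= 0.0 or p_pool >= 1.0:
            reject(chrom, pos, "MONOMORPHIC")
            continue
        if min(p_pool, 1.0 - p_pool) < config.maf_min:
            reject(chrom, pos, "MAF")
            continue
        if config.hwe_filter_alpha is not None and config.ploidy == 2:
            n_hom_alt = int((dos == 2).sum())
            n_het = int((dos == 1).sum())
            n_hom_ref = int((dos == 0).sum())
            p_hwe = hwe_exact_pvalue(n_hom_alt, n_het, n_hom_ref, side=config.hwe_side)
            if p_hwe < config.hwe_filter_alpha:
                reject(chrom, pos, "HWE")
                continue
        chroms.append(chrom)
        positions.append(pos)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    vcf.close()

    if not rows:
        raise ValueError("no SNPs passed filtering")
    for reason, n in sorted(counts.items()):
        logger.info("filtered %d sites: %s", n, reason)
    return GenotypeData(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=np.vstack(rows),
        samples=samples,
        is_female=is_female,
        ploidy=config.ploidy,
        n_input=n_input,
        filter_counts=counts,
        filter_records=records,
    )


def _counts_for_labels(data: GenotypeData, is_female: np.ndarray):
    """Per-site per-sex allele counts for a given sex-label assignment."""
    dos = data.dosage
    ok = dos >= 0
    dos0 = np.where(ok, dos, 0)
    if data.ploidy == 1:
        dos0 = (dos0 > 0).astype(np.int64)
    k_f = dos0[:, is_female].sum(axis=1)
    k_m = dos0[:, ~is_female].sum(axis=1)
    n_f = data.ploidy * ok[:, is_female].sum(axis=1)
    n_m = data.ploidy * ok[:, ~is_female].sum(axis=1)
    return k_f, n_f, k_m, n_m


def compute_scan(data: GenotypeData) -> pd.DataFrame:
    """Per-SNP between-sex F̂_ST, theoretical p-value, and null-CDF quantile.

    Each SNP's own missingness-aware harmonic-mean sample size n_H enters
    its null, so sites with different completeness are each referred to the
    correct χ²(1)/(2 n_H) distribution.
    """
    k_f, n_f, k_m, n_m = _counts_for_labels(data, data.is_female)
    fst, n_h = fst_from_counts(k_f, n_f, k_m, n_m)
    x = 2.0 * n_h * fst
    return pd.DataFrame(
        {
            "chrom": data.chrom,
            "pos": data.pos,
            "ref": data.ref,
            "alt": data.alt,
            "p_hat_f": k_f / n_f,
            "p_hat_m": k_m / n_m,
            "n_f": n_f,
            "n_m": n_m,
            "n_H": n_h,
            "fst": fst,
            "p_value": chi2.sf(x, df=1),
            "null_quantile": chi2.cdf(x, df=1),
        }
    )


@dataclass
class PermutationResult:
    """Per-replicate summaries of sex-label permutations.

    ``bin_counts[b, j]`` is the number of SNPs whose permuted null-CDF value
    fell in quantile bin j on replicate b; ``mean_fst`` the per-replicate
    mean F̂_ST; ``tail_counts`` the per-replicate counts above each
    theoretical (1 - alpha) null quantile.
    """

    B: int
    bins: int
    bin_counts: np.ndarray
    mean_fst: np.ndarray
    tail_counts: dict[float, np.ndarray]
    seed: int


def permute_scan(
    data: GenotypeData,
    B: int = 1000,
    seed: int = 0,
    bins: int = 100,
    alphas: tuple[float, ...] = (0.05, 0.01),
    chunk: int = 100,
) -> PermutationResult:
    """Recompute the scan under B random permutations of the sex labels.

    The permutation unit is the individual (both gene copies and the
    missingness pattern move together) and each replicate preserves the
    observed number of females and males. Per-site n_H is recomputed per
    replicate. Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    dos = data.dosage
    ok = dos >= 0
    dos0 = np.where(ok, dos, 0)
    if data.ploidy == 1:
        dos0 = (dos0 > 0).astype(np.int64)
    dos0 = dos0.astype(np.float64)
    okf = ok.astype(np.float64)
    k_tot = dos0.sum(axis=1)
    ok_tot = okf.sum(axis=1)
    n_female = int(data.is_female.sum())
    n_samples = len(data.samples)

    bin_counts = np.zeros((B, bins), dtype=np.int64)
    mean_fst = np.empty(B)
    tail_counts = {a: np.empty(B, dtype=np.int64) for a in alphas}
    crit = {a: chi2.ppf(1.0 - a, df=1) for a in alphas}

    done = 0
    while done < B:
        b = min(chunk, B - done)
        F = np.zeros((n_samples, b))
        for j in range(b):
            idx = rng.permutation(n_samples)[:n_female]
            F[idx, j] = 1.0
        k_f = dos0 @ F
        ok_f = okf @ F
        n_f = data.ploidy * ok_f
        n_m = data.ploidy * (ok_tot[:, None] - ok_f)
        k_m = k_tot[:, None] - k_f
        with np.errstate(divide="ignore", invalid="ignore"):
            p_f = k_f / n_f
            p_m = k_m / n_m
            pbar = 0.5 * (p_f + p_m)
            denom = 4.0 * pbar * (1.0 - pbar)
            fst = np.where(denom > 0, (p_f - p_m) ** 2 / denom, np.nan)
            n_h = 2.0 * n_f * n_m / (n_f + n_m)
        x = 2.0 * n_h * fst
        q = chi2.cdf(x, df=1)
        valid = np.isfinite(q)
        idx_bin = np.minimum((q * bins).astype(np.int64), bins - 1)
        for j in range(b):
            v = valid[:, j]
            bin_counts[done + j] = np.bincount(idx_bin[v, j], minlength=bins)
            mean_fst[done + j] = np.nanmean(fst[:, j])
            for a in alphas:
                tail_counts[a][done + j] = int((x[v, j] > crit[a]).sum())
        done += b

    return PermutationResult(
        B=B, bins=bins, bin_counts=bin_counts, mean_fst=mean_fst,
        tail_counts=tail_counts, seed=seed,
    )


def quantile_enrichment(
    scan: pd.DataFrame,
    permuted: PermutationResult | None = None,
    bins: int = 100,
) -> pd.DataFrame:
    """Observed vs null SNP counts within equal-probability null quantile bins.

    Bin edges are the theoretical null's quantile boundaries evaluated
    through each SNP's own null CDF, so the theoretical expectation is
    exactly uniform (N / bins per bin) regardless of per-site sample sizes.
    Ratios above one in the upper bins indicate an excess of differentiated
    SNPs. Bins with zero mean permuted count yield a missing ratio.
    """
    if permuted is not None and permuted.bins != bins:
        raise ValueError("permutation result was binned with a different bin count")
    q = scan["null_quantile"].to_numpy()
    valid = np.isfinite(q)
    idx = np.minimum((q[valid] * bins).astype(np.int64), bins - 1)
    observed = np.bincount(idx, minlength=bins)
    n = int(valid.sum())
    expected = n / bins
    edges = np.arange(bins + 1) / bins
    out = pd.DataFrame(
        {
            "bin": np.arange(bins),
            "q_lo": edges[:-1],
            "q_hi": edges[1:],
            "observed": observed,
            "expected_theoretical": expected,
            "ratio_theoretical": observed / expected,
        }
    )
    if permuted is not None:
        perm_mean = permuted.bin_counts.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(perm_mean > 0, observed / perm_mean, np.nan)
        out["permuted_mean"] = perm_mean
        out["ratio_permuted"] = ratio
    return out


@dataclass(frozen=True)
class TailTestResult:
    alpha: float
    n: int
    observed: int
    expected: float
    statistic: float
    p_value: float
    enriched: bool
    mode: str = "theoretical"


def tail_test(
    scan: pd.DataFrame,
    alpha: float,
    mode: str = "theoretical",
    permuted: PermutationResult | None = None,
) -> TailTestResult:
    """χ² test of tail occupancy above the theoretical (1 - alpha) null quantile.

    ``theoretical`` (default): one-degree-of-freedom goodness-of-fit of the
    observed above/below split against the analytic expectation alpha·N.
    ``permuted``: 2x2 contingency test of observed against pooled permuted
    tail counts. The enrichment direction (observed above expectation) is
    reported alongside the two-sided p-value.
    """
    q = scan["null_quantile"].to_numpy()
    valid = np.isfinite(q)
    n = int(valid.sum())
    observed = int((q[valid] > 1.0 - alpha).sum())
    expected = alpha * n
    if n < 1.0 / alpha:
        warnings.warn(
            f"fewer than 1/alpha = {1 / alpha:.0f} SNPs; tail test has little meaning",
            UserWarning,
            stacklevel=2,
        )
    if mode == "theoretical":
        below, exp_below = n - observed, n - expected
        statistic = (observed - expected) ** 2 / expected + (below - exp_below) ** 2 / exp_below
        p = float(chi2.sf(statistic, df=1))
    elif mode == "permuted":
        if permuted is None or alpha not in permuted.tail_counts:
            raise ValueError("permuted mode requires a PermutationResult covering alpha")
        perm_above = int(permuted.tail_counts[alpha].sum())
        perm_total = n * permuted.B
        table = np.array(
            [[observed, n - observed], [perm_above, perm_total - perm_above]]
        )
        statistic, p, _, _ = chi2_contingency(table, correction=False)
        statistic, p = float(statistic), float(p)
    else:
        raise ValueError("mode must be 'theoretical' or 'permuted'")
    return TailTestResult(
        alpha=alpha, n=n, observed=observed, expected=expected,
        statistic=statistic, p_value=p, enriched=observed > expected, mode=mode,
    )


@dataclass(frozen=True)
class MeanInflationResult:
    observed_mean: float
    permuted_mean: float
    permuted_sd: float
    p_value: float
    B: int


def mean_inflation_test(scan: pd.DataFrame, permuted: PermutationResult) -> MeanInflationResult:
    """Permutation test of mean F̂_ST inflation.

    p = (1 + #{permutation means ≥ observed mean}) / (1 + B), one-sided;
    the +1 smoothing means the p-value can never be exactly zero.
    """
    obs = float(np.nanmean(scan["fst"].to_numpy()))
    ge = int((permuted.mean_fst >= obs).sum())
    p = (1 + ge) / (1 + permuted.B)
    return MeanInflationResult(
        observed_mean=obs,
        permuted_mean=float(permuted.mean_fst.mean()),
        permuted_sd=float(permuted.mean_fst.std(ddof=1)) if permuted.B > 1 else float("nan"),
        p_value=p,
        B=permuted.B,
    )


@dataclass(frozen=True)
class FdrEstimate:
    alpha: float
    observed_fraction: float
    fdr: float
    true_positive_fraction: float
    deflated: bool = False


def estimate_fdr(f_obs: float, alpha: float) -> FdrEstimate:
    """Enrichment-implied false-discovery arithmetic for a null tail.

    If a fraction ``f_obs`` of SNPs falls above the theoretical
    (1 - alpha) quantile, the tail's false positives number alpha·N, so
    FDR = alpha / f_obs and the true-positive fraction is 1 - alpha/f_obs
    = (r - 1)/r for enrichment ratio r = f_obs / alpha. Deflated tails
    (f_obs < alpha) clamp to FDR = 1 with a flag.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 <= f_obs <= 1.0:
        raise ValueError("observed tail fraction must be in [0, 1]")
    if f_obs < alpha:
        return FdrEstimate(
            alpha=alpha, observed_fraction=f_obs, fdr=1.0,
            true_positive_fraction=0.0, deflated=True,
        )
    fdr = alpha / f_obs
    return FdrEstimate(
        alpha=alpha, observed_fraction=f_obs, fdr=fdr,
        true_positive_fraction=1.0 - fdr,
    )


@dataclass
class ScanResult:
    """Complete output of :func:`run_scan`."""

    config: ScanConfig
    scan: pd.DataFrame
    enrichment: pd.DataFrame
    tail_tests: list[TailTestResult]
    mean_inflation: MeanInflationResult
    fdr: list[FdrEstimate]
    filter_counts: dict[str, int]
    n_input: int
    n_retained: int


def run_scan(
    vcf_path: str | Path,
    sexmap_path: str | Path,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Full pipeline: load → scan → permute → enrichment, tail, mean, FDR."""
    config = config or ScanConfig()
    data = load_genotypes(vcf_path, sexmap_path, config)
    scan = compute_scan(data)
    permuted = permute_scan(
        data,
        B=config.permutations,
        seed=config.seed,
        bins=config.quantile_bins,
        alphas=config.alphas,
    )
    enrichment = quantile_enrichment(scan, permuted, bins=config.quantile_bins)
    tails = [tail_test(scan, a) for a in config.alphas]
    mean_res = mean_inflation_test(scan, permuted)
    n = len(scan)
    fdrs = [estimate_fdr(t.observed / t.n, t.alpha) for t in tails]
    return ScanResult(
        config=config,
        scan=scan,
        enrichment=enrichment,
        tail_tests=tails,
        mean_inflation=mean_res,
        fdr=fdrs,
        filter_counts=data.filter_counts,
        n_input=data.n_input,
        n_retained=n,
    )


def write_report(result: ScanResult, prefix: str | Path) -> dict[str, Path]:
    """Write the per-SNP table, per-bin table, JSON summary, and filter log.

    Produces ``<prefix>.snps.tsv``, ``<prefix>.bins.tsv``,
    ``<prefix>.summary.json`` and ``<prefix>.filters.log``; floats are
    written with 6 significant digits. Rerunning with the same config and
    seed reproduces the files exactly.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "snps": Path(f"{prefix}.snps.tsv"),
        "bins": Path(f"{prefix}.bins.tsv"),
        "summary": Path(f"{prefix}.summary.json"),
        "filters": Path(f"{prefix}.filters.log"),
    }
    try:
        result.scan.to_csv(paths["snps"], sep="\t", index=False, float_format="%.6g")
        result.enrichment.to_csv(paths["bins"], sep="\t", index=False, float_format="%.6g")
        summary = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else (str(v) if isinstance(v, Path) else v))
                for k, v in asdict(result.config).items()
            },
            "n_input": result.n_input,
            "n_retained": result.n_retained,
            "filter_counts": result.filter_counts,
            "tail_tests": [asdict(t) for t in result.tail_tests],
            "mean_inflation": asdict(result.mean_inflation),
            "fdr": [asdict(f) for f in result.fdr],
        }
        with open(paths["summary"], "w") as fh:
            json.dump(summary, fh, indent=2)
        with open(paths["filters"], "w") as fh:
            fh.write(f"input_sites\t{result.n_input}\n")
            fh.write(f"retained\t{result.n_retained}\n")
            for reason, count in sorted(result.filter_counts.items()):
                fh.write(f"{reason}\t{count}\n")
    except OSError as exc:
        raise OSError(f"failed writing report under {prefix}: {exc}") from exc
    return paths
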