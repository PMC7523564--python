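"""Tests for the genome-scan pipeline: loading, permutation, enrichment, FDR."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from sexscan import (
    PanelConfig,
    ScanConfig,
    compute_scan,
    estimate_fdr,
    hwe_exact_pvalue,
    load_genotypes,
    mean_inflation_test,
    permute_scan,
    quantile_enrichment,
    run_scan,
    simulate_fst_panel,
    tail_test,
    write_report,
    write_vcf_fixture,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
)


def _write_handcrafted_vcf(tmp_path):
    """Six-sample VCF exercising each filter reason exactly once."""
    samples = ["F0", "F1", "F2", "M0", "M1", "M2"]
    rows = [
        # multiallelic -> NOT_BIALLELIC_SNP
        ("1", 100, "A", "C,G", ["0/1"] * 6),
        # 4/6 missing under max_missing=0.5 -> MISSING
        ("1", 200, "A", "C", ["./.", "./.", "./.", "./.", "0/1", "0/1"]),
        # inside exclusion BED interval [249, 251) -> EXCLUDED_REGION
        ("1", 250, "A", "C", ["0/1"] * 6),
        # all hom-ref -> MONOMORPHIC
        ("1", 300, "A", "C", ["0/0"] * 6),
        # one alt copy of twelve: MAF 1/12 < 0.2 -> MAF
        ("1", 400, "A", "C", ["0/1", "0/0", "0/0", "0/0", "0/0", "0/0"]),
        # retained, equal frequencies between sexes
        ("1", 500, "A", "C", ["0/1", "0/1", "0/0", "0/1", "0/1", "0/0"]),
        # retained, sex-divergent
        ("1", 600, "A", "C", ["1/1", "1/1", "0/1", "0/0", "0/0", "0/1"]),
    ]
    lines = [VCF_HEADER + "\t".join(samples)]
    for chrom, pos, ref, alt, gts in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    vcf = tmp_path / "hand.vcf"
    vcf.write_text("\n".join(lines) + "\n")
    sexmap = tmp_path / "hand.sex.tsv"
    sexmap.write_text("".join(f"{s}\t{'F' if s.startswith('F') else 'M'}\n" for s in samples))
    bed = tmp_path / "excl.bed"
    bed.write_text("1\t249\t251\n")
    return vcf, sexmap, bed


class TestLoading:
    def test_filter_reasons_and_conservation(self, tmp_path):
        vcf, sexmap, bed = _write_handcrafted_vcf(tmp_path)
        cfg = ScanConfig(maf_min=0.2, max_missing=0.5, exclude_bed=bed)
        data = load_genotypes(vcf, sexmap, cfg)
        assert data.filter_counts == {
            "NOT_BIALLELIC_SNP": 1,
            "MISSING": 1,
            "EXCLUDED_REGION": 1,
            "MONOMORPHIC": 1,
            "MAF": 1,
        }
        # every input site is retained or logged exactly once
        assert data.n_sites + sum(data.filter_counts.values()) == data.n_input
        assert list(data.pos) == [500, 600]

    def test_sample_missing_from_sexmap_is_error(self, tmp_path):
        vcf, sexmap, _ = _write_handcrafted_vcf(tmp_path)
        sexmap.write_text("F0\tF\nF1\tF\nM0\tM\nM1\tM\n")
        with pytest.raises(ValueError, match="not in sex map"):
            load_genotypes(vcf, sexmap, ScanConfig())

    def test_unknown_sexmap_entries_warn(self, tmp_path):
        vcf, sexmap, _ = _write_handcrafted_vcf(tmp_path)
        sexmap.write_text(sexmap.read_text() + "GHOST\tF\n")
        with pytest.warns(UserWarning, match="not present in VCF"):
            load_genotypes(vcf, sexmap, ScanConfig(maf_min=0.0))

    def test_hwe_filter(self, tmp_path):
        vcf, sexmap, _ = _write_handcrafted_vcf(tmp_path)
        # site 600 has 2 hom-alt, 2 het, 2 hom-ref in perfect HW; site 500 too.
        data = load_genotypes(
            vcf, sexmap, ScanConfig(maf_min=0.2, hwe_filter_alpha=0.9)
        )
        # with an absurdly high alpha both retained sites get HWE-tested
        assert data.n_sites + sum(data.filter_counts.values()) == data.n_input


class TestHweExact:
    def test_matches_direct_combinatorial_oracle(self):
        """Exact HWE p-value agrees with the conditional probability computed
        directly from factorials (independent arithmetic route)."""
        n_aa, n_ab, n_bb = 3, 21, 76
        n = n_aa + n_ab + n_bb
        na = 2 * n_aa + n_ab
        nb = 2 * n - na

        from fractions import Fraction

        def prob(het):
            hom_a = (na - het) // 2
            hom_b = n - hom_a - het
            ways = Fraction(
                math.factorial(n),
                math.factorial(hom_a) * math.factorial(het) * math.factorial(hom_b),
            ) * 2**het
            return float(ways * Fraction(math.factorial(na) * math.factorial(nb),
                                         math.factorial(2 * n)))

        hets = range(na % 2, min(na, nb) + 1, 2)
        probs = {h: prob(h) for h in hets}
        p_obs = probs[n_ab]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
        assert hwe_exact_pvalue(n_aa, n_ab, n_bb) == pytest.approx(expected, rel=1e-9)

    def test_sidedness(self):
        # strong heterozygote excess: small p on the excess side, large on deficit
        assert hwe_exact_pvalue(0, 50, 50, side="excess") < 0.01
        assert hwe_exact_pvalue(0, 50, 50, side="deficit") > 0.99

    def test_hw_proportions_not_rejected(self):
        assert hwe_exact_pvalue(25, 50, 25) > 0.5


class TestComputeScan:
    def test_equal_frequencies_give_zero(self, tmp_path):
        vcf, sexmap, bed = _write_handcrafted_vcf(tmp_path)
        data = load_genotypes(vcf, sexmap, ScanConfig(maf_min=0.2, exclude_bed=bed))
        scan = compute_scan(data)
        site = scan[scan.pos == 500].iloc[0]
        assert site.fst == 0.0 and site.null_quantile == 0.0 and site.p_value == 1.0
        diverged = scan[scan.pos == 600].iloc[0]
        assert diverged.fst > 0

    def test_per_snp_nh_reflects_missingness(self, tmp_path):
        panel = simulate_fst_panel(PanelConfig(n_neutral=100, n_sa=0, seed=13))
        write_vcf_fixture(panel, 30, tmp_path / "m", seed=14, missing_rate=0.2)
        data = load_genotypes(
            tmp_path / "m.vcf", tmp_path / "m.sexmap.tsv",
            ScanConfig(maf_min=0.0, max_missing=0.9),
        )
        scan = compute_scan(data)
        assert scan.n_H.nunique() > 1
        expected = 2 * scan.n_f * scan.n_m / (scan.n_f + scan.n_m)
        assert np.allclose(scan.n_H, expected)


@pytest.fixture(scope="module")
def small_scan(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("perm")
    panel = simulate_fst_panel(PanelConfig(n_neutral=2000, n_sa=0, seed=21))
    write_vcf_fixture(panel, 30, tmp / "p", seed=22, missing_rate=0.05)
    data = load_genotypes(tmp / "p.vcf", tmp / "p.sexmap.tsv", ScanConfig())
    return data, compute_scan(data)


class TestPermutation:
    def test_preserves_sample_counts_and_is_deterministic(self, small_scan):
        data, scan = small_scan
        a = permute_scan(data, B=3, seed=5)
        b = permute_scan(data, B=3, seed=5)
        assert np.array_equal(a.bin_counts, b.bin_counts)
        assert np.array_equal(a.mean_fst, b.mean_fst)
        # every replicate bins every valid SNP exactly once
        assert (a.bin_counts.sum(axis=1) == data.n_sites).all()

    def test_permuted_distribution_matches_theoretical_tails(self, small_scan):
        """Permuted F̂_ST conforms to the theoretical null: tail occupancy
        above the (1 - alpha) null quantile averages alpha across replicates."""
        data, _ = small_scan
        perm = permute_scan(data, B=60, seed=6, alphas=(0.05, 0.01))
        n = data.n_sites
        frac05 = perm.tail_counts[0.05].mean() / n
        frac01 = perm.tail_counts[0.01].mean() / n
        assert frac05 == pytest.approx(0.05, abs=0.01)
        assert frac01 == pytest.approx(0.01, abs=0.005)

    def test_enrichment_bins_conserve_snps(self, small_scan):
        data, scan = small_scan
        perm = permute_scan(data, B=5, seed=1)
        enr = quantile_enrichment(scan, perm)
        assert enr.observed.sum() == data.n_sites
        assert len(enr) == 100

    def test_observed_close_to_permuted_on_null_data(self, small_scan):
        data, scan = small_scan
        perm = permute_scan(data, B=60, seed=2)
        enr = quantile_enrichment(scan, perm)
        occupied = enr[enr.permuted_mean >= 10]
        # observed counts scatter around permuted means with multinomial noise
        z = (occupied.observed - occupied.permuted_mean) / np.sqrt(occupied.permuted_mean)
        assert np.mean(z**2) < 3.0


class TestTailTest:
    def _fake_scan(self, n, n_above, alpha):
        q = np.full(n, 0.5)
        q[:n_above] = 1.0 - alpha / 2
        return pd.DataFrame({"null_quantile": q, "fst": q})

    def test_exact_expectation_gives_zero_statistic(self):
        scan = self._fake_scan(10_000, 100, 0.01)
        res = tail_test(scan, 0.01)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # 1500 of 1e5 above the 1% tail: chi2 = 500^2/1000 + 500^2/99000
        res = tail_test(self._fake_scan(100_000, 1500, 0.01), 0.01)
        assert res.statistic == pytest.approx(252.525, abs=0.01)
        assert res.p_value < 1e-15
        assert res.enriched

    def test_small_scan_warns(self):
        with pytest.warns(UserWarning, match="little meaning"):
            tail_test(self._fake_scan(50, 1, 0.01), 0.01)


class TestMeanInflation:
    def test_p_never_zero_and_positive_control(self, tmp_path):
        panel = simulate_fst_panel(
            PanelConfig(n_neutral=500, n_sa=500, s_dist="fixed", s_avg=1.0, seed=31)
        )
        write_vcf_fixture(panel, 100, tmp_path / "sa", seed=32)
        data = load_genotypes(tmp_path / "sa.vcf", tmp_path / "sa.sexmap.tsv", ScanConfig())
        scan = compute_scan(data)
        perm = permute_scan(data, B=39, seed=33)
        res = mean_inflation_test(scan, perm)
        assert res.p_value == pytest.approx(1 / 40)  # minimum attainable, never zero
        assert res.observed_mean > res.permuted_mean


class TestFdrArithmetic:
    def test_worked_example(self):
        res = estimate_fdr(0.02, 0.01)
        assert res.fdr == pytest.approx(0.5)
        assert res.true_positive_fraction == pytest.approx(0.5)

    def test_enrichment_ratio_to_true_positives(self):
        # ratio 1.5 at the 1% tail -> a third of tail SNPs are true positives
        res = estimate_fdr(1.5 * 0.01, 0.01)
        assert res.true_positive_fraction == pytest.approx(1 / 3)

    def test_no_signal_and_deflation(self):
        assert estimate_fdr(0.01, 0.01).fdr == 1.0
        res = estimate_fdr(0.005, 0.01)
        assert res.fdr == 1.0 and res.deflated

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr(0.02, 0.0)
        with pytest.raises(ValueError):
            estimate_fdr(1.5, 0.01)


class TestReport:
    def test_roundtrip_and_determinism(self, tmp_path):
        panel = simulate_fst_panel(PanelConfig(n_neutral=800, n_sa=0, seed=41))
        write_vcf_fixture(panel, 25, tmp_path / "r", seed=42)
        cfg = ScanConfig(permutations=20, seed=43)
        result = run_scan(tmp_path / "r.vcf", tmp_path / "r.sexmap.tsv", cfg)
        paths = write_report(result, tmp_path / "out" / "scan")
        summary = json.loads(paths["summary"].read_text())
        assert summary["n_retained"] == result.n_retained
        assert summary["fdr"][0]["fdr"] == result.fdr[0].fdr
        # filter log conservation
        log = dict(
            line.split("\t") for line in paths["filters"].read_text().splitlines()
        )
        counted = sum(int(v) for k, v in log.items() if k not in {"input_sites", "retained"})
        assert int(log["retained"]) + counted == int(log["input_sites"])
        # rerun reproduces files byte-for-byte
        result2 = run_scan(tmp_path / "r.vcf", tmp_path / "r.sexmap.tsv", cfg)
        paths2 = write_report(result2, tmp_path / "out2" / "scan")
        assert paths["snps"].read_bytes() == paths2["snps"].read_bytes()
        assert paths["summary"].read_bytes() == paths2["summary"].read_bytes()
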