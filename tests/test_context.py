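"""Tests for trinucleotide context, GC-window, and gene-density analyses."""

import numpy as np
import pytest

from ma_mutkit.context import (
    ALL_CONTEXTS,
    collapse_trinucleotide,
    context_label,
    g_test_uniformity,
    gc_window_rates,
    gene_density_rates,
    genome_context_counts,
    trinucleotide_rates,
    z_test_context,
)
from ma_mutkit.records import MutationCall, classify_mutation
from ma_mutkit.simulate import TreatmentSpec, simulate_ma


def snv_at(reference, chrom, pos1, sample="s1"):
    ref = reference.chromosomes[chrom][pos1 - 1]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    _, _, sclass = classify_mutation(ref, alt)
    return MutationCall(chrom=chrom, pos=pos1, ref=ref, alt=alt, mtype="SNV",
                        length=0, sample_id=sample, spectrum_class=sclass)


class TestCollapse:
    def test_collapse_idempotent(self):
        from itertools import product
        for tri in ("".join(t) for t in product("ACGT", repeat=3)):
            once = collapse_trinucleotide(tri)
            assert collapse_trinucleotide(once) == once
            assert once[1] in "AC"

    def test_32_collapsed_contexts(self):
        assert len(ALL_CONTEXTS) == 32

    def test_label_form(self):
        assert context_label("TAT") == "tAt"
        assert context_label("ATA") == "tAt"  # reverse complement pools


class TestTrinucleotideRates:
    def test_counts_sum_and_denominators(self, small_reference):
        rng = np.random.default_rng(0)
        calls = []
        for chrom in small_reference.chrom_names:
            sites = np.where(small_reference.callable_mask[chrom])[0]
            for p in rng.choice(sites[5:-5], size=100, replace=False):
                calls.append(snv_at(small_reference, chrom, int(p) + 1))
        table, excluded = trinucleotide_rates(calls, small_reference, 10, 1)
        assert table["count"].sum() + excluded == len(calls)
        # every genomic trinucleotide lands in exactly one collapsed context
        counts = genome_context_counts(small_reference)
        callable_inner = sum(
            int(m[1:-1].sum()) for m in small_reference.callable_mask.values()
        )
        assert sum(counts.values()) == callable_inner

    def test_single_call_rate_arithmetic(self, small_reference):
        chrom = "chr1"
        sites = np.where(small_reference.callable_mask[chrom])[0]
        call = snv_at(small_reference, chrom, int(sites[50]) + 1)
        table, _ = trinucleotide_rates([call], small_reference, 10, 1)
        seq = small_reference.chromosomes[chrom]
        tri = seq[sites[50] - 1 : sites[50] + 2]
        row = table.set_index("context").loc[context_label(tri)]
        assert row["count"] == 1
        assert row["rate"] == pytest.approx(1 / (row["available_sites"] * 10))

    def test_contig_end_calls_excluded(self, small_reference):
        call = snv_at(small_reference, "chr1", 1)
        table, excluded = trinucleotide_rates([call], small_reference, 10, 1)
        assert excluded == 1
        assert table["count"].sum() == 0

    def test_empty_input_all_zero(self, small_reference):
        table, _ = trinucleotide_rates([], small_reference, 10, 1)
        assert (table["count"] == 0).all()


class TestGTest:
    def test_balanced_counts_g_zero(self):
        g, p = g_test_uniformity([5, 5])
        assert g == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_extreme(self):
        g, p = g_test_uniformity([10, 0], [0.5, 0.5])
        assert g == pytest.approx(2 * 10 * np.log(2), rel=1e-6)
        assert p == pytest.approx(1.96e-4, rel=0.02)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            g_test_uniformity([0, 0, 0])

    def test_bad_expected_rejected(self):
        with pytest.raises(ValueError):
            g_test_uniformity([1, 2], [0.5, 0.6])

    def test_type_one_error_calibration(self):
        """Null multinomial draws reject at ~alpha (chi-square reference)."""
        rng = np.random.default_rng(5)
        alpha = 0.05
        rejections = 0
        reps = 1000
        for _ in range(reps):
            counts = rng.multinomial(160, np.full(16, 1 / 16))
            _, p = g_test_uniformity(counts)
            rejections += p < alpha
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)


class TestZTest:
    def test_equal_proportions(self):
        z, p = z_test_context(10, 1000, 100, 10_000)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            z_test_context(1, 0, 1, 100)

    def test_depleted_focal_sign(self):
        z, p = z_test_context(0, 100_000, 500, 100_000)
        assert z < 0
        assert p < 1

    def test_agrees_with_exact_binomial_at_adequate_counts(self):
        """Normal approximation vs exact binomial, both counts >= ~50."""
        for k1, n1, k2, n2 in [(60, 10_000, 500, 100_000), (80, 20_000, 350, 100_000)]:
            z, p = z_test_context(k1, n1, k2, n2)
            from scipy import stats
            pool = (k1 + k2) / (n1 + n2)
            exact = stats.binomtest(k1, n1, pool).pvalue
            assert p == pytest.approx(exact, rel=0.15)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(6)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            k1 = rng.binomial(5000, 0.01)
            k2 = rng.binomial(50_000, 0.01)
            _, p = z_test_context(k1, 5000, k2, 50_000)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestGcWindows:
    def test_zero_calls_all_zero(self, small_reference):
        out = gc_window_rates([], small_reference, g=10)
        assert (out["rate"] == 0).all()

    def test_rate_formula(self, small_reference):
        out = gc_window_rates([], small_reference, g=10)
        # plant 3 calls into the most populated bin
        target = out.sort_values("m", ascending=False).iloc[0]["bin"]
        # find windows in that bin
        calls = []
        seq = small_reference.chromosomes["chr1"]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        found = 0
        for wi in range(len(seq) // 1000):
            gc = float(((arr[wi * 1000 : (wi + 1) * 1000] == b"G") | (arr[wi * 1000 : (wi + 1) * 1000] == b"C")).mean())
            if int(gc / 0.005) == target and found < 3:
                calls.append(snv_at(small_reference, "chr1", wi * 1000 + 500))
                found += 1
        out2 = gc_window_rates(calls, small_reference, g=10)
        row = out2.set_index("bin").loc[target]
        assert row["n"] == found
        assert row["rate"] == pytest.approx(found / (row["m"] * 10 * 1000))

    def test_total_conservation(self, small_reference):
        rng = np.random.default_rng(2)
        calls = [
            snv_at(small_reference, "chr1", int(p) + 1)
            for p in rng.choice(np.where(small_reference.callable_mask["chr1"])[0][: 90_000], 50, replace=False)
        ]
        out = gc_window_rates(calls, small_reference, g=10)
        assert out["n"].sum() == 50  # all calls fall inside tiled windows

    def test_oversized_window_rejected(self, small_reference):
        with pytest.raises(ValueError):
            gc_window_rates([], small_reference, g=10, window=10**7)


class TestGeneDensity:
    def test_gene_free_bins_only(self, small_reference):
        """Mutations planted only outside genes at high density -> low group."""
        bins_summary, bins = gene_density_rates([], small_reference, g=10, bin_size=10_000)
        empty_bins = bins[bins["gene_bp"] <= bins["gene_bp"].median()]
        calls = []
        for r in empty_bins.head(10).itertuples(index=False):
            pos = r.start + (r.end - r.start) // 2
            calls.append(snv_at(small_reference, r.chrom, pos + 1))
        summary, _ = gene_density_rates(calls, small_reference, g=10, bin_size=10_000)
        assert summary["rate_high"] == 0.0
        assert summary["rate_low"] > 0

    def test_uniform_null_no_bias(self, small_reference):
        """Uniformly planted mutations: |rate_high - rate_low| small vs null spread."""
        rng = np.random.default_rng(3)
        diffs = []
        for s in range(10):
            calls = []
            for chrom in small_reference.chrom_names:
                sites = np.where(small_reference.callable_mask[chrom])[0]
                for p in rng.choice(sites, 60, replace=False):
                    calls.append(snv_at(small_reference, chrom, int(p) + 1))
            summary, _ = gene_density_rates(calls, small_reference, g=10, bin_size=10_000)
            diffs.append(summary["rate_high"] - summary["rate_low"])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-12

    def test_too_few_bins_rejected(self, small_reference):
        with pytest.raises(ValueError):
            gene_density_rates([], small_reference, g=10, bin_size=10**6)


class TestPowerAgainstPlantedBias:
    def test_low_density_enrichment_detected(self, megabase_reference):
        """2x planting weight in low-density bins yields a significant t test."""
        rng = np.random.default_rng(4)
        _, bins = gene_density_rates([], megabase_reference, g=10, bin_size=100_000)
        median = bins["gene_bp"].median()
        low = bins[bins["gene_bp"] <= median]
        high = bins[bins["gene_bp"] > median]
        hits = 0
        for s in range(5):
            calls = []
            for _ in range(1000):
                use_low = rng.random() < 2 / 3  # 2x weight on low-density bins
                grp = low if use_low else high
                r = grp.iloc[rng.integers(0, len(grp))]
                pos = int(rng.integers(r["start"], r["end"]))
                calls.append(snv_at(megabase_reference, r["chrom"], pos + 1))
            summary, _ = gene_density_rates(calls, megabase_reference, g=10, bin_size=100_000)
            if summary["p"] < 0.05 and summary["rate_low"] > summary["rate_high"]:
                hits += 1
        assert hits >= 4
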