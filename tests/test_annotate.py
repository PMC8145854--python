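"""Tests for region annotation, fitness-affecting rate, and Ka/Ks counting."""

import numpy as np
import pytest

from ma_mutkit.annotate import (
    CODON_TABLE,
    annotate_mutation,
    build_gene_models,
    fitness_rate,
    kaks_ratio,
    ng86_site_counts,
    region_frequency_table,
    region_site_counts,
)
from ma_mutkit.records import MutationCall, classify_mutation


def call_at(reference, chrom, pos1, alt=None):
    ref = reference.chromosomes[chrom][pos1 - 1]
    if alt is None:
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    mtype, length, sclass = classify_mutation(ref, alt)
    return MutationCall(chrom=chrom, pos=pos1, ref=ref, alt=alt, mtype=mtype,
                        length=length, sample_id="s1", spectrum_class=sclass)


@pytest.fixture(scope="module")
def models(small_reference):
    return build_gene_models(small_reference)


class TestAnnotateMutation:
    def test_synonymous_vs_nonsynonymous_by_genetic_code(self, small_reference, models):
        """Check coding-effect labels against direct codon translation."""
        m = next(mm for mm in models if mm.strand == "+")
        cds = m.cds_sequence(small_reference.chromosomes)
        seg_start = sorted(m.cds)[0][0]
        checked = 0
        for offset in range(3, 60):
            pos0 = seg_start + offset
            codon_i, frame = offset // 3, offset % 3
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            for alt in "ACGT":
                if alt == small_reference.chromosomes[m.chrom][pos0]:
                    continue
                new = codon[:frame] + alt + codon[frame + 1 :]
                ann = annotate_mutation(
                    call_at(small_reference, m.chrom, pos0 + 1, alt),
                    small_reference, models,
                )
                if CODON_TABLE[new] == CODON_TABLE[codon]:
                    assert ann.region == "exonic:synonymous"
                elif CODON_TABLE[new] == "*":
                    assert ann.region == "exonic:stopgain"
                else:
                    assert ann.region == "exonic:nonsynonymous"
                checked += 1
        assert checked > 50

    def test_minus_strand_gene_translation(self, small_reference, models):
        m = next(mm for mm in models if mm.strand == "-")
        cds = m.cds_sequence(small_reference.chromosomes)
        assert cds.startswith("ATG")
        assert CODON_TABLE[cds[-3:]] == "*"
        assert all(CODON_TABLE[cds[i:i + 3]] != "*" for i in range(3, len(cds) - 3, 3))

    def test_frameshift_deletion_in_cds(self, small_reference, models):
        m = next(mm for mm in models if mm.strand == "+")
        s = sorted(m.cds)[0][0] + 6
        seq = small_reference.chromosomes[m.chrom]
        c = MutationCall(chrom=m.chrom, pos=s + 1, ref=seq[s : s + 2], alt=seq[s],
                        mtype="deletion", length=1, sample_id="s1")
        ann = annotate_mutation(c, small_reference, models)
        assert ann.region == "exonic:frameshift"
        c3 = MutationCall(chrom=m.chrom, pos=s + 1, ref=seq[s : s + 4], alt=seq[s],
                         mtype="deletion", length=3, sample_id="s1")
        assert annotate_mutation(c3, small_reference, models).region == "exonic:nonframeshift"

    def test_te_class_outside_genes(self, small_reference, models):
        iv = small_reference.te_intervals("chr1")
        pos0 = int(iv[0][0]) + 5
        ann = annotate_mutation(call_at(small_reference, "chr1", pos0 + 1), small_reference, models)
        assert ann.region in ("TE", "upstream", "downstream")  # TEs can abut gene flanks
        assert ann.in_te

    def test_intergenic_far_from_everything(self, small_reference, models):
        # scan for a position > 1 kb from genes and outside TEs
        f = small_reference.features
        occupied = np.zeros(small_reference.spec.chrom_length, dtype=bool)
        for r in f[f["chrom"] == "chr1"].itertuples(index=False):
            lo = max(r.start - 1100, 0)
            hi = min(r.end + 1100, len(occupied))
            occupied[lo:hi] = True
        pos0 = int(np.where(~occupied)[0][100])
        ann = annotate_mutation(call_at(small_reference, "chr1", pos0 + 1), small_reference, models)
        assert ann.region == "intergenic"

    def test_annotation_stable_under_model_reordering(self, small_reference, models):
        rng = np.random.default_rng(0)
        sites = np.where(small_reference.callable_mask["chr1"])[0]
        shuffled = list(models)[::-1]
        for p in rng.choice(sites[10:-10], size=50, replace=False):
            c = call_at(small_reference, "chr1", int(p) + 1)
            a1 = annotate_mutation(c, small_reference, models)
            a2 = annotate_mutation(c, small_reference, shuffled)
            assert a1.region == a2.region


class TestRegionTable:
    def test_counts_sum_to_total(self, small_reference, models):
        rng = np.random.default_rng(1)
        sites = np.where(small_reference.callable_mask["chr1"])[0]
        calls = [call_at(small_reference, "chr1", int(p) + 1)
                 for p in rng.choice(sites[10:-10], size=80, replace=False)]
        annotated = [(c, annotate_mutation(c, small_reference, models)) for c in calls]
        table = region_frequency_table(
            annotated, region_site_counts(small_reference, models), g=10, n_samples=1
        )
        assert table["n"].sum() == len(calls)

    def test_frequency_arithmetic(self, small_reference, models):
        f = small_reference.features
        occupied = np.zeros(small_reference.spec.chrom_length, dtype=bool)
        for r in f[f["chrom"] == "chr1"].itertuples(index=False):
            occupied[max(r.start - 1100, 0) : min(r.end + 1100, len(occupied))] = True
        free = np.where(~occupied)[0]
        calls = [call_at(small_reference, "chr1", int(p) + 1) for p in free[:5]]
        annotated = [(c, annotate_mutation(c, small_reference, models)) for c in calls]
        table = region_frequency_table(
            annotated, region_site_counts(small_reference, models), g=10, n_samples=1
        )
        assert table.set_index("region").loc["intergenic", "mean_frequency"] == pytest.approx(0.5)

    def test_region_site_counts_partition_callable(self, small_reference, models):
        counts = region_site_counts(small_reference, models)
        assert sum(counts.values()) == small_reference.n_callable()


class TestFitnessRate:
    def test_arithmetic(self):
        assert fitness_rate(1e-8, 2 * 10**7) == pytest.approx(0.264)

    def test_zero_rate(self):
        assert fitness_rate(0.0, 10**7) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fitness_rate(1e-8, 0)
        with pytest.raises(ValueError):
            fitness_rate(1e-8, 100, constraint=0.0)


def brute_force_sites(codon):
    """Fraction of the 9 single changes per codon that are synonymous."""
    aa = CODON_TABLE[codon]
    syn = nonsyn = 0
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            other = codon[:p] + b + codon[p + 1 :]
            if CODON_TABLE[other] == aa:
                syn += 1
            else:
                nonsyn += 1
    return nonsyn / 3, syn / 3


class TestNeiGojobori:
    def test_toy_cds_site_counts(self):
        n, s = ng86_site_counts("ATGAAA")
        bn1, bs1 = brute_force_sites("ATG")
        bn2, bs2 = brute_force_sites("AAA")
        assert n == pytest.approx(bn1 + bn2)
        assert s == pytest.approx(bs1 + bs2)

    def test_counts_match_enumeration_on_random_cds(self):
        rng = np.random.default_rng(7)
        non_stop = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
        for _ in range(20):
            codons = [non_stop[i] for i in rng.integers(0, len(non_stop), size=rng.integers(5, 100))]
            cds = "".join(codons)
            n, s = ng86_site_counts(cds)
            bn = bs = 0.0
            for c in codons:
                x, y = brute_force_sites(c)
                bn += x
                bs += y
            assert n == pytest.approx(bn)
            assert s == pytest.approx(bs)
            assert n + s == pytest.approx(3 * len(codons))

    def test_only_synonymous_changes_gives_zero_ka(self):
        res = kaks_ratio(0, 1, ["ATGAAATTTTAA"[:9]])
        assert res["Ka"] == 0.0
        assert res["ratio"] == 0.0

    def test_no_synonymous_changes_undefined_ratio(self):
        res = kaks_ratio(3, 0, ["ATGAAATTT"])
        assert res["ratio"] is None

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            kaks_ratio(1, 1, ["ATGTAAAAATTT"])
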