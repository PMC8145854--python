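"""Unit and property tests for the de novo mutation filter cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ma_mutkit.filters import FilterConfig, apply_hard_filters, identify_de_novo
from ma_mutkit.records import (
    SPECTRUM_CLASSES,
    VariantRecord,
    classify_mutation,
    spectrum_class,
)

from oracles import brute_force_cascade

CONFIG = FilterConfig()


def make_record(**kw):
    base = dict(
        chrom="chr1", pos=1000, ref="C", alt="T",
        qd=30.0, fs=1.0, mq=60.0, mq_rank_sum=None, read_pos_rank_sum=None,
        dp=40, adf=20, adr=20, gt="hom_alt", sample_id="s1",
    )
    base.update(kw)
    return VariantRecord(**base)


def background_ref(chrom, pos, ref="C"):
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref[0]]
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref[0], alt=alt, qd=None, fs=None, mq=60.0,
        mq_rank_sum=None, read_pos_rank_sum=None, dp=30, adf=0, adr=0,
        gt="hom_ref", sample_id="bg",
    )


class TestHardFilters:
    @pytest.mark.parametrize(
        "kwargs,expect_pass,reason",
        [
            (dict(qd=1.5), False, "QD<2.0"),
            (dict(qd=30.0, fs=1.0, mq=60.0, dp=40), True, None),
            (dict(fs=61.0), False, "FS>60.0"),
            (dict(mq=19.9), False, "MQ<20.0"),
            (dict(mq_rank_sum=-13.0), False, "MQRankSum<-12.5"),
            (dict(read_pos_rank_sum=-8.5), False, "ReadPosRankSum<-8.0"),
            (dict(dp=7, adf=3, adr=4), False, "DP<8"),
            (dict(ref="AT", alt="A", dp=4, adf=2, adr=2), False, "DP<5"),
            (dict(ref="AT", alt="A", fs=150.0), True, None),  # indel FS cap is 200
            (dict(ref="AT", alt="A", read_pos_rank_sum=-15.0), True, None),
        ],
    )
    def test_threshold_predicates(self, kwargs, expect_pass, reason):
        ok, why = apply_hard_filters(make_record(**kwargs), CONFIG)
        assert ok is expect_pass
        assert why == reason

    def test_absent_rank_sums_do_not_fail(self):
        ok, _ = apply_hard_filters(
            make_record(mq_rank_sum=None, read_pos_rank_sum=None), CONFIG
        )
        assert ok

    def test_negative_depth_rejected_as_malformed(self):
        with pytest.raises(ValueError):
            make_record(dp=-1)


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,mtype,length,sclass",
        [
            ("G", "A", "SNV", 0, "C:G>T:A"),
            ("C", "T", "SNV", 0, "C:G>T:A"),
            ("A", "C", "SNV", 0, "A:T>C:G"),
            ("T", "A", "SNV", 0, "A:T>T:A"),
            ("ATT", "A", "deletion", 2, None),
            ("C", "CTG", "insertion", 2, None),
        ],
    )
    def test_examples(self, ref, alt, mtype, length, sclass):
        assert classify_mutation(ref, alt) == (mtype, length, sclass)

    def test_multi_nucleotide_substitution_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation("AC", "GT")

    @given(
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
    )
    def test_complement_collapse_symmetry(self, ref, alt):
        comp = str.maketrans("ACGT", "TGCA")
        if ref == alt:
            return
        assert spectrum_class(ref, alt) == spectrum_class(
            ref.translate(comp), alt.translate(comp)
        )
        assert spectrum_class(ref, alt) in SPECTRUM_CLASSES


class TestCascadeExamples:
    def test_snv_near_indel_removed(self):
        snv = make_record(pos=1000)
        indel = make_record(pos=1009, ref="CAT", alt="C")
        bg = [background_ref("chr1", 1000), background_ref("chr1", 1009)]
        calls, audit = identify_de_novo([snv, indel], bg)
        assert {c.pos for c in calls} == {1009}
        assert audit.set_index("pos").loc[1000, "reason"] == "near_indel"

    def test_snv_ten_bp_from_indel_kept(self):
        snv = make_record(pos=1000)
        indel = make_record(pos=1010, ref="CA", alt="C")
        bg = [background_ref("chr1", 1000), background_ref("chr1", 1010)]
        calls, _ = identify_de_novo([snv, indel], bg)
        assert {c.pos for c in calls} == {1000, 1010}

    def test_close_indel_pair_both_removed(self):
        a = make_record(pos=1000, ref="CAT", alt="C")
        b = make_record(pos=1017, ref="TG", alt="T")  # 14 bases between spans
        bg = [background_ref("chr1", 1000), background_ref("chr1", 1017, "T")]
        calls, audit = identify_de_novo([a, b], bg)
        assert calls == []
        assert set(audit["reason"]) == {"indel_pair"}

    def test_background_variant_subtracted(self):
        rec = make_record()
        bg_variant = make_record(sample_id="bg")
        calls, audit = identify_de_novo([rec], [bg_variant])
        assert calls == []
        assert audit.loc[0, "reason"] == "in_background"

    def test_background_het_site_removed(self):
        rec = make_record()
        bg = make_record(sample_id="bg", gt="het", adf=10, adr=10)
        calls, audit = identify_de_novo([rec], [bg])
        assert calls == []
        assert audit.loc[0, "reason"] == "background_heterozygous"

    def test_no_background_coverage_excluded(self):
        calls, audit = identify_de_novo([make_record()], [])
        assert calls == []
        assert audit.loc[0, "reason"] == "no_background_support"

    def test_missing_background_table_is_error(self):
        with pytest.raises(ValueError, match="background"):
            identify_de_novo([make_record()], None)

    def test_duplicate_records_rejected(self):
        rec = make_record()
        with pytest.raises(ValueError, match="duplicate"):
            identify_de_novo([rec, make_record()], [background_ref("chr1", 1000)])

    def test_single_strand_snv_removed(self):
        rec = make_record(adf=40, adr=0)
        calls, audit = identify_de_novo([rec], [background_ref("chr1", 1000)])
        assert calls == []
        assert audit.loc[0, "reason"] == "single_strand_support"

    def test_heterozygous_genotype_removed(self):
        rec = make_record(gt="het", adf=10, adr=10)
        calls, audit = identify_de_novo([rec], [background_ref("chr1", 1000)])
        assert calls == []
        assert audit.loc[0, "reason"] == "heterozygous_genotype"

    def test_repeat_context_indel_flagged_not_dropped(self):
        # deleting "AT" with another "AT" immediately downstream
        seq = "G" * 999 + "CATAT" + "G" * 100
        rec = make_record(pos=1000, ref="CAT", alt="C")
        calls, _ = identify_de_novo(
            [rec], [background_ref("chr1", 1000)], reference={"chr1": seq}
        )
        assert len(calls) == 1
        assert calls[0].needs_validation


def random_instance(rng, n_records=500):
    """A randomized cascade instance exercising every filter branch."""
    records, background = [], []
    used = set()
    for i in range(n_records):
        while True:
            pos = int(rng.integers(100, 500_000))
            if all(abs(pos - p) > 40 for p in used) or rng.random() < 0.15:
                break
        used.add(pos)
        is_indel = rng.random() < 0.25
        if is_indel:
            ln = int(rng.integers(1, 4))
            if rng.random() < 0.6:
                ref = "C" + "AT" * 2
                ref = ref[: ln + 1]
                alt = ref[0]
            else:
                alt = "C" + "GA" * 2
                alt = alt[: ln + 1]
                ref = alt[0]
        else:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("A", "G")
        gt = rng.choice(["hom_alt", "hom_alt", "hom_alt", "het"])
        dp = int(rng.choice([3, 6, 9, 20, 40]))
        n_alt = dp if gt == "hom_alt" else dp // 2
        if rng.random() < 0.1:
            n_alt = int(dp * 0.6)  # low alt fraction despite hom call
        adf = int(rng.integers(0, n_alt + 1))
        rec = VariantRecord(
            chrom="chr1", pos=pos, ref=ref, alt=alt,
            qd=float(rng.choice([1.0, 2.5, 30.0])),
            fs=float(rng.choice([1.0, 65.0, 210.0])),
            mq=float(rng.choice([15.0, 25.0, 60.0])),
            mq_rank_sum=None if rng.random() < 0.5 else float(rng.choice([-13.0, 0.0])),
            read_pos_rank_sum=None if rng.random() < 0.5 else float(rng.choice([-21.0, -9.0, 0.0])),
            dp=dp, adf=adf, adr=n_alt - adf, gt=str(gt), sample_id="s1",
        )
        records.append(rec)
        roll = rng.random()
        if roll < 0.6:
            background.append(background_ref("chr1", pos, ref))
        elif roll < 0.7:
            background.append(
                VariantRecord(**{**rec.__dict__, "sample_id": "bg"})
            )
        elif roll < 0.8:
            background.append(
                VariantRecord(
                    chrom="chr1", pos=pos, ref=ref, alt=alt, qd=20.0, fs=1.0,
                    mq=60.0, mq_rank_sum=None, read_pos_rank_sum=None,
                    dp=30, adf=8, adr=7, gt="het", sample_id="bg",
                )
            )
        # else: no background coverage
    # drop accidental duplicate (pos, alt) records
    seen, uniq = set(), []
    for r in records:
        if (r.pos, r.alt) not in seen:
            seen.add((r.pos, r.alt))
            uniq.append(r)
    return uniq, background


class TestCascadeProperties:
    def test_matches_brute_force_oracle(self):
        """Cascade output equals an exhaustive per-criterion scan."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            records, background = random_instance(rng, 500)
            calls, _ = identify_de_novo(records, background, CONFIG)
            got = {(c.chrom, c.pos, c.ref, c.alt) for c in calls}
            want = brute_force_cascade(records, background, CONFIG)
            assert got == want

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        records, background = random_instance(rng, 300)
        calls, _ = identify_de_novo(records, background, CONFIG)
        surviving = [
            r for r in records
            if (r.chrom, r.pos, r.ref, r.alt) in {(c.chrom, c.pos, c.ref, c.alt) for c in calls}
        ]
        again, _ = identify_de_novo(surviving, background, CONFIG)
        assert {(c.chrom, c.pos, c.ref, c.alt) for c in again} == {
            (c.chrom, c.pos, c.ref, c.alt) for c in calls
        }

    def test_order_independent(self):
        rng = np.random.default_rng(2)
        records, background = random_instance(rng, 300)
        calls, _ = identify_de_novo(records, background, CONFIG)
        shuffled = list(records[::-1])
        calls2, _ = identify_de_novo(shuffled, background, CONFIG)
        assert {c.key for c in calls} == {c.key for c in calls2}

    @pytest.mark.parametrize(
        "field,delta",
        [("snv_qd_min", 5.0), ("snv_dp_min", 5), ("snv_fs_max", -30.0), ("min_alt_fraction", 0.15)],
    )
    def test_tightening_thresholds_never_adds_calls(self, field, delta):
        rng = np.random.default_rng(3)
        records, background = random_instance(rng, 300)
        base, _ = identify_de_novo(records, background, CONFIG)
        tight = FilterConfig(**{**CONFIG.__dict__, field: getattr(CONFIG, field) + delta})
        tightened, _ = identify_de_novo(records, background, tight)
        assert {c.key for c in tightened} <= {c.key for c in base}
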