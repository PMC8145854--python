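"""De novo mutation identification: hard filters plus the stringent cascade.

Candidate variant calls from an MA (mutation accumulation) sample are reduced
to homozygous de novo mutations by (i) GATK-style hard-filter thresholds with
separate SNV and indel parameter sets, then (ii) a cascade of stringent
criteria: minimum depth in sample and ancestral background, alt support on
both strands for SNVs, subtraction of background variants and of sites
heterozygous in the background, removal of SNVs adjacent to indels, removal
of close indel pairs, and a homozygosity requirement. Indels sitting in a
local tandem-repeat context are kept but flagged ``needs_validation`` (their
confirmation requires orthogonal evidence such as Sanger sequencing).

The cascade is deterministic and order-independent: each criterion is defined
against either the raw input or a fixed earlier survivor set, never against
the mutable output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import MutationCall, VariantRecord, call_from_record


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds and cascade parameters."""

    snv_qd_min: float = 2.0
    snv_fs_max: float = 60.0
    snv_mq_min: float = 20.0
    snv_mqrs_min: float = -12.5
    snv_rprs_min: float = -8.0
    snv_dp_min: int = 8
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_mq_min: float = 20.0
    indel_rprs_min: float = -20.0
    indel_dp_min: int = 5
    background_dp_min: int = 5
    snv_indel_distance: int = 10  # SNVs closer than this to an indel are dropped
    indel_pair_interval: int = 20  # indel pairs this close (or closer) are dropped
    min_alt_fraction: float = 0.8  # homozygosity evidence requirement

    def __post_init__(self):
        if self.snv_indel_distance <= 0 or self.indel_pair_interval <= 0:
            raise ValueError("distances must be positive")


def apply_hard_filters(rec: VariantRecord, config: FilterConfig = FilterConfig()):
    """Return (passed, first-failing-predicate-or-None) for one record.

    Absent rank-sum annotations never fail: they are undefined for sites
    without reference-supporting reads (typical of true homozygous variants).
    """
    def defined(x):
        return x is not None

    if rec.is_snv:
        checks = [
            (defined(rec.qd) and rec.qd < config.snv_qd_min, f"QD<{config.snv_qd_min}"),
            (defined(rec.fs) and rec.fs > config.snv_fs_max, f"FS>{config.snv_fs_max}"),
            (defined(rec.mq) and rec.mq < config.snv_mq_min, f"MQ<{config.snv_mq_min}"),
            (
                defined(rec.mq_rank_sum) and rec.mq_rank_sum < config.snv_mqrs_min,
                f"MQRankSum<{config.snv_mqrs_min}",
            ),
            (
                defined(rec.read_pos_rank_sum)
                and rec.read_pos_rank_sum < config.snv_rprs_min,
                f"ReadPosRankSum<{config.snv_rprs_min}",
            ),
            (rec.dp < config.snv_dp_min, f"DP<{config.snv_dp_min}"),
        ]
    else:
        checks = [
            (defined(rec.qd) and rec.qd < config.indel_qd_min, f"QD<{config.indel_qd_min}"),
            (defined(rec.fs) and rec.fs > config.indel_fs_max, f"FS>{config.indel_fs_max}"),
            (defined(rec.mq) and rec.mq < config.indel_mq_min, f"MQ<{config.indel_mq_min}"),
            (
                defined(rec.read_pos_rank_sum)
                and rec.read_pos_rank_sum < config.indel_rprs_min,
                f"ReadPosRankSum<{config.indel_rprs_min}",
            ),
            (rec.dp < config.indel_dp_min, f"DP<{config.indel_dp_min}"),
        ]
    for failed, reason in checks:
        if failed:
            return False, reason
    return True, None


def _span_gap(a: VariantRecord, b: VariantRecord) -> int:
    """Bases strictly between two records' reference spans (0 if touching/overlapping)."""
    a1, a2 = a.span
    b1, b2 = b.span
    if a2 < b1:
        return b1 - a2 - 1
    if b2 < a1:
        return a1 - b2 - 1
    return 0


def _snv_indel_distance(snv: VariantRecord, indel: VariantRecord) -> int:
    s1, s2 = indel.span
    if s1 <= snv.pos <= s2:
        return 0
    return s1 - snv.pos if snv.pos < s1 else snv.pos - s2


def is_repeat_context(rec: VariantRecord, reference: Optional[dict]) -> bool:
    """Whether an indel's inserted/deleted unit tandemly repeats at the site."""
    if reference is None or rec.is_snv:
        return False
    seq = reference.get(rec.chrom)
    if seq is None:
        return False
    if len(rec.ref) > len(rec.alt):
        unit = rec.ref[len(rec.alt):]
        site_end = rec.pos - 1 + len(rec.ref)  # 0-based end of deleted span
    else:
        unit = rec.alt[len(rec.ref):]
        site_end = rec.pos  # 0-based position right after the anchor base
    nxt = seq[site_end : site_end + len(unit)]
    prv = seq[max(0, rec.pos - len(unit)) : rec.pos]
    return nxt == unit or prv == unit


def identify_de_novo(
    sample_records: Iterable[VariantRecord],
    background_records: Iterable[VariantRecord],
    config: FilterConfig = FilterConfig(),
    reference: Optional[dict] = None,
    lineage_id: str = "",
    treatment: str = "",
):
    """Run the full cascade for one MA sample against the ancestral background.

    ``background_records`` must cover every candidate site: hom-ref records
    carry the background depth that certifies a site as non-variant; variant
    and heterozygous background records trigger subtraction. Sites without
    background coverage at the required depth are treated as uncallable.

    Returns (calls, audit) where audit is a DataFrame with one row per input
    record recording the decision and the first applicable reason.
    """
    records = list(sample_records)
    if background_records is None:
        raise ValueError("background table is mandatory for de novo identification")
    background = list(background_records)

    seen = set()
    for rec in records:
        key = (rec.sample_id, rec.chrom, rec.pos, rec.alt)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)

    bg_by_site: dict = {}
    for b in background:
        bg_by_site.setdefault((b.chrom, b.pos), []).append(b)

    # indels as called in the raw input: discarded ones still poison nearby SNVs
    all_indels = [r for r in records if r.is_indel]

    decisions = {}

    def decide(rec, status, reason):
        decisions[id(rec)] = (status, reason)

    # stage 1: hard filters
    survivors = []
    for rec in records:
        ok, reason = apply_hard_filters(rec, config)
        if ok:
            survivors.append(rec)
        else:
            decide(rec, "fail", f"hard_filter:{reason}")

    # stage 2: background support and subtraction
    stage2 = []
    for rec in survivors:
        site_bg = bg_by_site.get((rec.chrom, rec.pos), [])
        variant_match = any(
            b.ref == rec.ref and b.alt == rec.alt and b.gt != "hom_ref" for b in site_bg
        )
        het_site = any(b.gt == "het" for b in site_bg)
        covered = any(
            b.dp >= config.background_dp_min and b.gt == "hom_ref" for b in site_bg
        )
        if het_site:
            decide(rec, "fail", "background_heterozygous")
        elif variant_match:
            decide(rec, "fail", "in_background")
        elif not covered:
            decide(rec, "fail", "no_background_support")
        else:
            stage2.append(rec)

    # stage 3: strand support (SNVs) and homozygosity
    stage3 = []
    for rec in stage2:
        if rec.is_snv and (rec.adf < 1 or rec.adr < 1):
            decide(rec, "fail", "single_strand_support")
        elif rec.gt != "hom_alt":
            decide(rec, "fail", "heterozygous_genotype")
        elif rec.alt_fraction < config.min_alt_fraction:
            decide(rec, "fail", "low_alt_fraction")
        else:
            stage3.append(rec)

    # stage 4: SNVs near any called indel (retained or discarded)
    stage4 = []
    for rec in stage3:
        if rec.is_snv and any(
            _snv_indel_distance(rec, ind) < config.snv_indel_distance
            for ind in all_indels
        ):
            decide(rec, "fail", "near_indel")
        else:
            stage4.append(rec)

    # stage 5: close indel pairs (both members dropped)
    indels4 = [r for r in stage4 if r.is_indel]
    bad = set()
    for i, a in enumerate(indels4):
        for b in indels4[i + 1 :]:
            if a.chrom == b.chrom and _span_gap(a, b) <= config.indel_pair_interval:
                bad.add(id(a))
                bad.add(id(b))
    final = []
    for rec in stage4:
        if id(rec) in bad:
            decide(rec, "fail", "indel_pair")
        else:
            decide(rec, "pass", None)
            final.append(rec)

    calls = []
    for rec in final:
        call = call_from_record(rec, lineage_id=lineage_id, treatment=treatment)
        call.needs_validation = is_repeat_context(rec, reference)
        calls.append(call)

    audit = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "decision": decisions[id(r)][0],
                "reason": decisions[id(r)][1],
            }
            for r in records
        ]
    )
    return calls, audit


def calls_to_frame(calls: Iterable[MutationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "mtype": c.mtype,
                "length": c.length,
                "sample_id": c.sample_id,
                "lineage_id": c.lineage_id,
                "treatment": c.treatment,
                "spectrum_class": c.spectrum_class,
                "needs_validation": c.needs_validation,
            }
            for c in calls
        ]
    )


def frame_to_calls(df: pd.DataFrame) -> list:
    return [
        MutationCall(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            mtype=row.mtype,
            length=int(row.length),
            sample_id=row.sample_id,
            lineage_id=getattr(row, "lineage_id", row.sample_id),
            treatment=getattr(row, "treatment", ""),
            spectrum_class=None if pd.isna(getattr(row, "spectrum_class", None)) else row.spectrum_class,
            needs_validation=bool(getattr(row, "needs_validation", False)),
        )
        for row in df.itertuples(index=False)
    ]
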