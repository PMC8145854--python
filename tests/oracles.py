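"""Independent brute-force reimplementations used as test oracles.

Deliberately naive: every criterion is checked by exhaustive scan with no
shared code or staging structure from the implementation under test.
"""

from math import comb


def brute_force_cascade(records, background, config, ref_seqs=None):
    """Exhaustive re-derivation of the accepted de novo record set."""
    def is_snv(r):
        return len(r.ref) == 1 and len(r.alt) == 1

    def span(r):
        return (r.pos, r.pos + len(r.ref) - 1)

    def hard_ok(r):
        if is_snv(r):
            if r.qd is not None and r.qd < config.snv_qd_min:
                return False
            if r.fs is not None and r.fs > config.snv_fs_max:
                return False
            if r.mq is not None and r.mq < config.snv_mq_min:
                return False
            if r.mq_rank_sum is not None and r.mq_rank_sum < config.snv_mqrs_min:
                return False
            if r.read_pos_rank_sum is not None and r.read_pos_rank_sum < config.snv_rprs_min:
                return False
            if r.dp < config.snv_dp_min:
                return False
        else:
            if r.qd is not None and r.qd < config.indel_qd_min:
                return False
            if r.fs is not None and r.fs > config.indel_fs_max:
                return False
            if r.mq is not None and r.mq < config.indel_mq_min:
                return False
            if r.read_pos_rank_sum is not None and r.read_pos_rank_sum < config.indel_rprs_min:
                return False
            if r.dp < config.indel_dp_min:
                return False
        return True

    def background_ok(r):
        site = [b for b in background if b.chrom == r.chrom and b.pos == r.pos]
        if any(b.ref == r.ref and b.alt == r.alt and b.gt != "hom_ref" for b in site):
            return False
        if any(b.gt == "het" for b in site):
            return False
        return any(b.gt == "hom_ref" and b.dp >= config.background_dp_min for b in site)

    def zygosity_ok(r):
        if r.gt != "hom_alt":
            return False
        return r.dp > 0 and (r.adf + r.adr) / r.dp >= config.min_alt_fraction

    def strand_ok(r):
        return (not is_snv(r)) or (r.adf >= 1 and r.adr >= 1)

    all_indels = [r for r in records if not is_snv(r)]

    def far_from_indels(r):
        if not is_snv(r):
            return True
        for ind in all_indels:
            if ind.chrom != r.chrom:
                continue
            s1, s2 = span(ind)
            d = 0 if s1 <= r.pos <= s2 else min(abs(r.pos - s1), abs(r.pos - s2))
            if d < config.snv_indel_distance:
                return False
        return True

    stage = [
        r
        for r in records
        if hard_ok(r) and background_ok(r) and strand_ok(r) and zygosity_ok(r)
        and far_from_indels(r)
    ]
    survivors = []
    for r in stage:
        if is_snv(r):
            survivors.append(r)
            continue
        close = False
        for other in stage:
            if other is r or is_snv(other) or other.chrom != r.chrom:
                continue
            a1, a2 = span(r)
            b1, b2 = span(other)
            gap = b1 - a2 - 1 if a2 < b1 else (a1 - b2 - 1 if b2 < a1 else 0)
            if gap <= config.indel_pair_interval:
                close = True
        if not close:
            survivors.append(r)
    return {(r.chrom, r.pos, r.ref, r.alt) for r in survivors}


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point masses <= observed."""
    row1 = a + b
    row2 = c + d
    col1 = a + c
    n = row1 + row2

    def pmf(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)
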