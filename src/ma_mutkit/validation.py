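"""Pipeline-validation experiments: planted-mutation recovery.

Two repeatable checks of the identification cascade:

* ``recover_planted_snvs`` — compare pipeline output against a planted SNV
  list by (chrom, pos, alt) and report the recovery fraction plus any calls
  not in the planted set (false positives).
* ``heterozygosity_recovery_test`` — plant truly homozygous SNVs, perturb a
  fraction of them so their genotype evidence looks heterozygous (the
  evidence-level analogue of read-level mutation injection), run the zygosity
  filter, and report the surviving fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import FilterConfig, identify_de_novo
from .genome import Reference
from .simulate import NoiseConfig, emit_variant_calls


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_false_positive: int
    accessible_nonvariant_sites: int

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_planted

    def to_dict(self):
        return {
            "n_planted": self.n_planted,
            "n_recovered": self.n_recovered,
            "recovery_fraction": self.recovery_fraction,
            "n_false_positive": self.n_false_positive,
            "accessible_nonvariant_sites": self.accessible_nonvariant_sites,
        }


def recover_planted_snvs(planted, calls, accessible_sites: int = 0) -> RecoveryReport:
    """Match pipeline output against a planted list by (chrom, pos, alt)."""
    planted_keys = {(c, p, a) for c, p, _r, a in planted}
    if not planted_keys:
        raise ValueError("empty planted list: recovery fraction undefined")
    call_keys = {(c.chrom, c.pos, c.alt) for c in calls}
    recovered = planted_keys & call_keys
    return RecoveryReport(
        n_planted=len(planted_keys),
        n_recovered=len(recovered),
        n_false_positive=len(call_keys - planted_keys),
        accessible_nonvariant_sites=max(accessible_sites - len(planted_keys), 0),
    )


def reference_snv_validation(
    reference: Reference,
    n_per_genome: int = 100,
    n_genomes: int = 6,
    dropout_probability: float = 0.0,
    seed: int = 0,
):
    """End-to-end planted-SNV recovery through emission and identification.

    Mirrors the planted-reference-mutation design: ``n_per_genome``
    substitutions per genome copy, evenly allocated per chromosome, positions
    independent between copies. ``dropout_probability`` removes each planted
    record from the emitted call table independently, emulating sites lost to
    alignment/calling; with it at zero the cascade must recover every mutation.
    """
    from .simulate import SimulatedMutation, plant_reference_snvs

    _copies, planted = plant_reference_snvs(reference, n_per_genome, n_genomes, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    reports = []
    for gi, muts in enumerate(planted):
        kept = [m for m in muts if rng.random() >= dropout_probability]
        truth = {
            f"sim{gi + 1}": [
                SimulatedMutation(c, p, r, a, "planted", 1) for c, p, r, a in kept
            ]
        }
        sample_records, background, _ = emit_variant_calls(
            reference, truth, NoiseConfig(), seed=seed * 1000 + gi
        )
        calls, _ = identify_de_novo(
            sample_records[f"sim{gi + 1}"], background,
            reference=reference.chromosomes,
        )
        reports.append(
            recover_planted_snvs(muts, calls, accessible_sites=reference.n_callable())
        )
    total = RecoveryReport(
        n_planted=sum(r.n_planted for r in reports),
        n_recovered=sum(r.n_recovered for r in reports),
        n_false_positive=sum(r.n_false_positive for r in reports),
        accessible_nonvariant_sites=sum(r.accessible_nonvariant_sites for r in reports),
    )
    return total, reports


def heterozygosity_recovery_test(
    n_planted_hom: int,
    p_het_evidence: float,
    seed: int = 0,
    config: FilterConfig = FilterConfig(),
) -> RecoveryReport:
    """Zygosity-filter recovery of truly homozygous SNVs.

    Each planted homozygous SNV independently presents heterozygous-like
    evidence (genotype 0/1, ~50% alt fraction) with probability
    ``p_het_evidence``; the zygosity filter then removes it. Expected
    recovery is therefore 1 - p_het_evidence.
    """
    if not 0.0 <= p_het_evidence <= 1.0:
        raise ValueError("p_het_evidence must be in [0, 1]")
    if n_planted_hom < 1:
        raise ValueError("need at least one planted SNV")
    from .records import VariantRecord

    rng = np.random.default_rng(seed)
    het_like = rng.random(n_planted_hom) < p_het_evidence
    records = []
    for i, het in enumerate(het_like):
        dp = 40
        alt_reads = dp // 2 if het else dp
        records.append(
            VariantRecord(
                chrom="chr1", pos=100 * (i + 1), ref="C", alt="T",
                qd=25.0, fs=2.0, mq=60.0, mq_rank_sum=None, read_pos_rank_sum=None,
                dp=dp, adf=alt_reads // 2, adr=alt_reads - alt_reads // 2,
                gt="het" if het else "hom_alt", sample_id="het_test",
            )
        )
    recovered = sum(
        1
        for r in records
        if r.gt == "hom_alt" and r.alt_fraction >= config.min_alt_fraction
    )
    return RecoveryReport(
        n_planted=n_planted_hom,
        n_recovered=recovered,
        n_false_positive=0,
        accessible_nonvariant_sites=0,
    )
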