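"""Overlap of de novo mutations with a natural-polymorphism panel.

De novo calls from all lineages are merged to unique sites; positional and
allele-identical overlap with a biallelic panel is counted and compared with
the expectation under random placement over accessible sites using a
two-sided Fisher's exact test (Bonferroni-corrected across variant types).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pysam
from scipy import stats


def left_normalize(pos: int, ref: str, alt: str):
    """Trim shared trailing then leading bases (minimal left-aligned form)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def merge_unique_mutations(calls):
    """Deduplicate calls by exact (chrom, pos, ref, alt) after normalization.

    Returns (unique_snvs, unique_indels) as sorted lists of keys. Conflicting
    reference alleles at one position are an input error.
    """
    snvs, indels = {}, {}
    ref_at: dict = {}
    for c in calls:
        pos, ref, alt = left_normalize(c.pos, c.ref, c.alt)
        key = (c.chrom, pos, ref, alt)
        site = (c.chrom, pos, len(ref) == 1 == len(alt))
        if site in ref_at and ref_at[site] != ref:
            raise ValueError(f"conflicting reference alleles at {c.chrom}:{pos}")
        ref_at[site] = ref
        (snvs if len(ref) == 1 == len(alt) else indels)[key] = True
    return sorted(snvs), sorted(indels)


def read_panel(path, biallelic_only: bool = True):
    """Read a polymorphism panel VCF into a list of (chrom, pos, ref, alt)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            alts = row.alts or ()
            if biallelic_only and len(alts) != 1:
                continue
            for alt in alts:
                pos, ref, alt = left_normalize(row.pos, row.ref, alt)
                out.append((row.chrom, pos, ref, alt))
    return out


@dataclass
class OverlapResult:
    n_unique: int
    n_positional_overlap: int
    n_identical: int
    panel_sites: int
    accessible_sites: int
    fisher_p: Optional[float] = None
    bonferroni_p: Optional[float] = None

    @property
    def expected_overlap(self) -> float:
        return self.n_unique * self.panel_sites / self.accessible_sites

    def to_dict(self):
        return {
            "n_unique": self.n_unique,
            "n_positional_overlap": self.n_positional_overlap,
            "n_identical": self.n_identical,
            "expected_overlap": self.expected_overlap,
            "fisher_p": self.fisher_p,
            "bonferroni_p": self.bonferroni_p,
        }


def overlap_with_panel(unique_keys, panel_keys, accessible_sites: int) -> OverlapResult:
    """Count positional and allele-identical overlap with the panel."""
    panel_pos = {(c, p) for c, p, _r, _a in panel_keys}
    panel_exact = set(panel_keys)
    positional = sum(1 for c, p, _r, _a in unique_keys if (c, p) in panel_pos)
    identical = sum(1 for k in unique_keys if k in panel_exact)
    return OverlapResult(
        n_unique=len(unique_keys),
        n_positional_overlap=positional,
        n_identical=identical,
        panel_sites=len(panel_pos),
        accessible_sites=accessible_sites,
    )


def overlap_significance(
    observed: int,
    n_unique: int,
    panel_sites: int,
    accessible_sites: int,
    n_tests: int = 2,
):
    """Two-sided Fisher's exact test of observed vs random-placement overlap.

    Table: [[overlap, non-overlapping uniques],
            [remaining panel sites, remaining accessible sites]].
    """
    if accessible_sites < panel_sites:
        raise ValueError("accessible_sites must be >= panel_sites")
    a = observed
    b = n_unique - observed
    c = panel_sites - observed
    d = accessible_sites - panel_sites - n_unique + observed
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in table [[{a},{b}],[{c},{d}]]")
    _odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), min(float(p) * n_tests, 1.0)


def classify_ancestral_derived(unique_keys, ancestral_positions, derived_positions):
    """Count unique mutations overlapping ancestral vs derived site sets.

    Site sets are (chrom, pos) collections and must be disjoint.
    """
    anc = set(ancestral_positions)
    der = set(derived_positions)
    if anc & der:
        raise ValueError("ancestral and derived site sets overlap")
    anc_hits = [k for k in unique_keys if (k[0], k[1]) in anc]
    der_hits = [k for k in unique_keys if (k[0], k[1]) in der]
    return {
        "n_ancestral": len(anc_hits),
        "n_derived": len(der_hits),
        "ancestral_hits": anc_hits,
        "derived_hits": der_hits,
    }
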