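"""Core record types: called variants and accepted de novo mutations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The six strand-collapsed single-base substitution classes.
SPECTRUM_CLASSES = (
    "C:G>T:A",
    "C:G>A:T",
    "C:G>G:C",
    "A:T>G:C",
    "A:T>T:A",
    "A:T>C:G",
)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_ALLELES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with its quality annotations and read evidence.

    ``pos`` is 1-based (as in VCF). Rank-sum annotations may be absent: they
    are undefined when a site has no reference-supporting reads.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qd: Optional[float]
    fs: Optional[float]
    mq: Optional[float]
    mq_rank_sum: Optional[float]
    read_pos_rank_sum: Optional[float]
    dp: int
    adf: int
    adr: int
    gt: str  # hom_ref | het | hom_alt
    sample_id: str

    def __post_init__(self):
        if self.dp < 0:
            raise ValueError(f"negative depth {self.dp} at {self.chrom}:{self.pos}")
        if self.adf < 0 or self.adr < 0 or self.adf + self.adr > self.dp:
            raise ValueError(
                f"strand alt depths ({self.adf},{self.adr}) inconsistent with DP={self.dp}"
            )
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"bad alleles {self.ref}>{self.alt}")
        if not (_ALLELES >= set(self.ref) and _ALLELES >= set(self.alt)):
            raise ValueError(f"alleles must be over ACGT: {self.ref}>{self.alt}")
        if self.gt not in ("hom_ref", "het", "hom_alt"):
            raise ValueError(f"unknown genotype label {self.gt}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv

    @property
    def span(self):
        """1-based inclusive reference span covered by the record."""
        return (self.pos, self.pos + len(self.ref) - 1)

    @property
    def alt_fraction(self) -> float:
        return (self.adf + self.adr) / self.dp if self.dp else 0.0


@dataclass
class MutationCall:
    """An accepted de novo mutation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mtype: str  # SNV | insertion | deletion
    length: int  # 0 for SNV
    sample_id: str
    lineage_id: str = ""
    treatment: str = ""
    spectrum_class: Optional[str] = None
    needs_validation: bool = False
    annotations: dict = field(default_factory=dict)

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_transition(self) -> Optional[bool]:
        if self.mtype != "SNV":
            return None
        return (self.ref, self.alt) in TRANSITIONS


def spectrum_class(ref: str, alt: str) -> str:
    """Collapse a single-base substitution into its six-class label."""
    if ref in "AC":
        r, a = ref, alt
    else:
        r, a = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    pair = {"A": "A:T", "C": "C:G"}[r]
    dest = {"A": "A:T", "C": "C:G", "G": "G:C", "T": "T:A"}[a]
    return f"{pair}>{dest}"


def classify_mutation(ref: str, alt: str):
    """Classify an allele pair as SNV/insertion/deletion.

    Returns (mtype, length, spectrum_class-or-None). Multi-nucleotide
    substitutions (equal lengths > 1) are rejected; they must be split into
    single-base records upstream.
    """
    if len(ref) == len(alt):
        if len(ref) != 1:
            raise ValueError(f"multi-nucleotide substitution {ref}>{alt}; split upstream")
        return "SNV", 0, spectrum_class(ref, alt)
    if len(ref) > len(alt):
        return "deletion", len(ref) - len(alt), None
    return "insertion", len(alt) - len(ref), None


def call_from_record(rec: VariantRecord, lineage_id="", treatment="") -> MutationCall:
    mtype, length, sclass = classify_mutation(rec.ref, rec.alt)
    return MutationCall(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=rec.alt,
        mtype=mtype,
        length=length,
        sample_id=rec.sample_id,
        lineage_id=lineage_id or rec.sample_id,
        treatment=treatment,
        spectrum_class=sclass,
    )
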