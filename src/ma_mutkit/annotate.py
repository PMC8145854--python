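"""Genomic-region annotation of mutations, fitness-affecting rate, and Ka/Ks.

Region classes follow a fixed precedence so every mutation gets exactly one
primary class: exonic/splicing > UTR > intronic > upstream/downstream >
ncRNA/pseudogene > TE > intergenic. Upstream/downstream means within 1 kb of
the transcription start/stop. Transposable-element membership is additionally
reported as a flag regardless of the primary class.

Coding SNVs are translated with the standard nuclear genetic code against the
annotated reading frame; CDS indels are frameshift iff length mod 3 != 0.
Ka/Ks uses Nei-Gojobori style site counting (equal rates among the three
possible changes at a site; changes to or from stop codons count as
nonsynonymous), with an optional Jukes-Cantor correction that is off by
default because the observed counts here are tiny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .genome import Reference, revcomp
from .rates import mutation_frequency, mutation_rate

CODON_TABLE = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    CODON_TABLE[stop] = "*"

REGION_CLASSES = (
    "exonic:synonymous",
    "exonic:nonsynonymous",
    "exonic:stopgain",
    "exonic:stoploss",
    "exonic:frameshift",
    "exonic:nonframeshift",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "ncRNA",
    "pseudogene",
    "TE",
    "intergenic",
)

FLANK = 1000  # upstream/downstream window, bp
SPLICE_MARGIN = 2  # bp into the intron counted as splicing


@dataclass
class RegionAnnotation:
    region: str
    gene_id: Optional[str] = None
    in_te: bool = False


@dataclass
class _GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list  # [(start, end)] genomic order
    utr5: list
    utr3: list

    @property
    def introns(self):
        parts = sorted(self.cds + self.utr5 + self.utr3)
        out = []
        for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def cds_sequence(self, chromosomes) -> str:
        seq = "".join(chromosomes[self.chrom][s:e] for s, e in sorted(self.cds))
        return seq if self.strand == "+" else revcomp(seq)


def build_gene_models(reference: Reference) -> list:
    models = []
    f = reference.features
    for gene_id, grp in f[f["type"] != "transposable_element"].groupby("gene_id"):
        gene = grp[grp["type"] == "gene"]
        if gene.empty:
            continue
        g = gene.iloc[0]
        models.append(
            _GeneModel(
                gene_id=gene_id,
                chrom=g["chrom"],
                start=int(g["start"]),
                end=int(g["end"]),
                strand=g["strand"],
                cds=[(int(r.start), int(r.end)) for r in grp[grp["type"] == "CDS"].itertuples(index=False)],
                utr5=[(int(r.start), int(r.end)) for r in grp[grp["type"] == "five_prime_UTR"].itertuples(index=False)],
                utr3=[(int(r.start), int(r.end)) for r in grp[grp["type"] == "three_prime_UTR"].itertuples(index=False)],
            )
        )
    return models


def _coding_effect(call, model: _GeneModel, chromosomes) -> str:
    """Classify a CDS mutation by its codon-level consequence."""
    if call.mtype != "SNV":
        return (
            "exonic:frameshift" if call.length % 3 != 0 else "exonic:nonframeshift"
        )
    cds_segs = sorted(model.cds)
    total = sum(e - s for s, e in cds_segs)
    pos0 = call.pos - 1
    offset = 0
    for s, e in cds_segs:
        if s <= pos0 < e:
            offset += pos0 - s
            break
        offset += e - s
    if model.strand == "-":
        offset = total - 1 - offset
    cds_seq = model.cds_sequence(chromosomes)
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length of {model.gene_id} not divisible by 3")
    alt_base = call.alt if model.strand == "+" else revcomp(call.alt)
    codon_i = offset // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[: offset % 3] + alt_base + codon[offset % 3 + 1 :]
    aa_old = CODON_TABLE[codon]
    aa_new = CODON_TABLE[new_codon]
    if aa_old == aa_new:
        return "exonic:synonymous"
    if aa_new == "*":
        return "exonic:stopgain"
    if aa_old == "*":
        return "exonic:stoploss"
    return "exonic:nonsynonymous"


def annotate_mutation(call, reference: Reference, models: Optional[list] = None) -> RegionAnnotation:
    """Assign the primary region class (documented precedence) to one call."""
    if models is None:
        models = build_gene_models(reference)
    pos0 = call.pos - 1
    in_te = reference.in_te(call.chrom, pos0)

    containing = [
        m for m in models if m.chrom == call.chrom and m.start <= pos0 < m.end
    ]
    for m in containing:
        if any(s <= pos0 < e for s, e in m.cds):
            return RegionAnnotation(_coding_effect(call, m, reference.chromosomes), m.gene_id, in_te)
    for m in containing:
        for s, e in m.introns:
            if s <= pos0 < e:
                if pos0 < s + SPLICE_MARGIN or pos0 >= e - SPLICE_MARGIN:
                    return RegionAnnotation("splicing", m.gene_id, in_te)
    for m in containing:
        if any(s <= pos0 < e for s, e in m.utr5):
            return RegionAnnotation("UTR5", m.gene_id, in_te)
        if any(s <= pos0 < e for s, e in m.utr3):
            return RegionAnnotation("UTR3", m.gene_id, in_te)
    for m in containing:
        if any(s <= pos0 < e for s, e in m.introns):
            return RegionAnnotation("intronic", m.gene_id, in_te)
    for m in models:
        if m.chrom != call.chrom:
            continue
        if m.strand == "+":
            up = (m.start - FLANK, m.start)
            down = (m.end, m.end + FLANK)
        else:
            up = (m.end, m.end + FLANK)
            down = (m.start - FLANK, m.start)
        if up[0] <= pos0 < up[1]:
            return RegionAnnotation("upstream", m.gene_id, in_te)
        if down[0] <= pos0 < down[1]:
            return RegionAnnotation("downstream", m.gene_id, in_te)
    if in_te:
        return RegionAnnotation("TE", None, True)
    return RegionAnnotation("intergenic", None, False)


def region_site_counts(reference: Reference, models: Optional[list] = None) -> dict:
    """Callable bases per primary region group (coding classes pooled as 'exonic')."""
    if models is None:
        models = build_gene_models(reference)
    counts = {}
    for chrom, seq in reference.chromosomes.items():
        n = len(seq)
        # priority codes: 0 intergenic, 1 TE, 2 up/down, 3 intronic, 4 splicing, 5 UTR, 6 exonic
        level = np.zeros(n, dtype=np.int8)
        for s, e in reference.te_intervals(chrom):
            level[s:e] = np.maximum(level[s:e], 1)
        for m in models:
            if m.chrom != chrom:
                continue
            for lo, hi in ((m.start - FLANK, m.start), (m.end, m.end + FLANK)):
                lo, hi = max(lo, 0), min(hi, n)
                level[lo:hi] = np.maximum(level[lo:hi], 2)
            for s, e in m.introns:
                level[s:e] = np.maximum(level[s:e], 3)
                level[s : s + SPLICE_MARGIN] = np.maximum(level[s : s + SPLICE_MARGIN], 4)
                level[max(e - SPLICE_MARGIN, s) : e] = np.maximum(level[max(e - SPLICE_MARGIN, s) : e], 4)
            for s, e in m.utr5 + m.utr3:
                level[s:e] = np.maximum(level[s:e], 5)
            for s, e in m.cds:
                level[s:e] = np.maximum(level[s:e], 6)
        mask = reference.callable_mask[chrom]
        names = ["intergenic", "TE", "flank", "intronic", "splicing", "UTR", "exonic"]
        for code, name in enumerate(names):
            counts[name] = counts.get(name, 0) + int(np.sum(mask & (level == code)))
    return counts


_REGION_GROUP = {
    "exonic:synonymous": "exonic",
    "exonic:nonsynonymous": "exonic",
    "exonic:stopgain": "exonic",
    "exonic:stoploss": "exonic",
    "exonic:frameshift": "exonic",
    "exonic:nonframeshift": "exonic",
    "splicing": "splicing",
    "UTR5": "UTR",
    "UTR3": "UTR",
    "intronic": "intronic",
    "upstream": "flank",
    "downstream": "flank",
    "ncRNA": "intergenic",
    "pseudogene": "intergenic",
    "TE": "TE",
    "intergenic": "intergenic",
}


def region_frequency_table(annotated_calls, site_counts: dict, g: int, n_samples: int) -> pd.DataFrame:
    """Per-region mean frequency m = n/g over samples and per-region SNV rate.

    ``annotated_calls`` is an iterable of (call, RegionAnnotation) pairs.
    """
    rows = []
    per_region_counts: dict = {}
    per_region_snvs: dict = {}
    for call, ann in annotated_calls:
        if ann.region not in REGION_CLASSES:
            raise ValueError(f"unknown region class {ann.region}")
        per_region_counts[ann.region] = per_region_counts.get(ann.region, 0) + 1
        if call.mtype == "SNV":
            per_region_snvs[ann.region] = per_region_snvs.get(ann.region, 0) + 1
    for region in REGION_CLASSES:
        n = per_region_counts.get(region, 0)
        group = _REGION_GROUP[region]
        sites = site_counts.get(group, 0)
        n_snv = per_region_snvs.get(region, 0)
        rows.append(
            {
                "region": region,
                "n": n,
                "mean_frequency": mutation_frequency(n, g) / n_samples,
                "snv_rate": mutation_rate(n_snv, g, sites) / n_samples if sites else 0.0,
            }
        )
    return pd.DataFrame(rows)


def fitness_rate(mu_coding: float, coding_sites: int, constraint: float = 0.66) -> float:
    """Diploid genomic rate of fitness-affecting coding mutations per generation.

    U = 2 x constraint x mu_coding x L_coding: the per-site coding rate scaled
    by the fraction of coding mutations under selection and diploid copy number.
    """
    if mu_coding < 0:
        raise ValueError("mu_coding must be >= 0")
    if coding_sites <= 0:
        raise ValueError("coding_sites must be > 0")
    if not 0 < constraint <= 1:
        raise ValueError("selective constraint must be in (0, 1]")
    return 2.0 * constraint * mu_coding * coding_sites


def fitness_rate_summary(per_lineage_mu_coding, coding_sites: int, constraint: float = 0.66):
    vals = [fitness_rate(mu, coding_sites, constraint) for mu in per_lineage_mu_coding]
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return {"mean": float(np.mean(vals)), "sem": sem, "per_lineage": vals}


def ng86_site_counts(cds_seq: str):
    """Nei-Gojobori synonymous/nonsynonymous site counts for one CDS.

    Each codon position contributes s/3 synonymous sites where s of its three
    possible single-base changes are synonymous; stop codons in the sequence
    are skipped (they encode no amino acid to conserve).
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    n_sites = s_sites = 0.0
    for i in range(0, len(cds_seq), 3):
        codon = cds_seq[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None or aa == "*":
            continue
        for p in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1 :]
                if CODON_TABLE[alt] == aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += (3 - syn) / 3.0
    return n_sites, s_sites


def kaks_ratio(n_nonsyn: int, n_syn: int, cds_seqs, jukes_cantor: bool = False) -> dict:
    """Ka/Ks from observed substitution counts and the CDS set's site counts."""
    n_sites = s_sites = 0.0
    for seq in cds_seqs:
        if "*" in [CODON_TABLE.get(seq[i : i + 3]) for i in range(0, len(seq) - 3, 3)]:
            raise ValueError("internal stop codon in CDS")
        n, s = ng86_site_counts(seq)
        n_sites += n
        s_sites += s
    pn = n_nonsyn / n_sites if n_sites else float("nan")
    ps = n_syn / s_sites if s_sites else float("nan")
    if jukes_cantor:
        ka = -0.75 * np.log(1 - 4 * pn / 3)
        ks = -0.75 * np.log(1 - 4 * ps / 3)
    else:
        ka, ks = pn, ps
    result = {"Ka": float(ka), "Ks": float(ks), "N_sites": n_sites, "S_sites": s_sites}
    result["ratio"] = float(ka / ks) if n_syn > 0 else None
    return result
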