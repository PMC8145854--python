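"""Readers and writers for the standard formats the toolkit exchanges.

FASTA goes through Biopython, VCF through pysam. GFF3 and BED for the small
fixed feature vocabulary used here are plain tab-separated tables handled
with pandas. Internal coordinates are 0-based half-open; GFF3/VCF on disk are
1-based per their specifications.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import VariantRecord

VCF_HEADER_LINES = [
    ('INFO', 'QD', '1', 'Float', 'Variant quality by depth'),
    ('INFO', 'FS', '1', 'Float', 'Phred-scaled strand bias (Fisher)'),
    ('INFO', 'MQ', '1', 'Float', 'RMS mapping quality'),
    ('INFO', 'MQRankSum', '1', 'Float', 'Mapping-quality rank-sum (alt vs ref reads)'),
    ('INFO', 'ReadPosRankSum', '1', 'Float', 'Read-position rank-sum (alt vs ref reads)'),
    ('INFO', 'DP', '1', 'Integer', 'Combined read depth'),
    ('FORMAT', 'GT', '1', 'String', 'Genotype'),
    ('FORMAT', 'AD', 'R', 'Integer', 'Allele depths'),
    ('FORMAT', 'DP', '1', 'Integer', 'Sample read depth'),
    ('FORMAT', 'ADF', '1', 'Integer', 'Forward-strand alt-allele read depth'),
    ('FORMAT', 'ADR', '1', 'Integer', 'Reverse-strand alt-allele read depth'),
]


def write_fasta(chromosomes: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(features: pd.DataFrame, path) -> None:
    """Emit features (internal 0-based half-open) as 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = f"ID={row.gene_id}" if row.type in ("gene", "transposable_element") else f"Parent={row.gene_id}"
            phase = "0" if row.type == "CDS" else "."
            fh.write(
                f"{row.chrom}\tma_mutkit\t{row.type}\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t{phase}\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 back into the internal 0-based half-open feature table."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start1", "end1", "score", "strand", "phase", "attrs"],
    )
    ids = df["attrs"].str.extract(r"(?:ID|Parent)=([^;]+)")[0]
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start1"] - 1,
            "end": df["end1"],
            "type": df["type"],
            "strand": df["strand"],
            "gene_id": ids,
        }
    )


def write_bed_mask(callable_mask: dict, path) -> None:
    """Callable intervals as BED (0-based half-open, matching internal coords)."""
    with open(path, "w") as fh:
        for chrom, mask in callable_mask.items():
            padded = np.concatenate([[False], mask, [False]])
            diff = np.diff(padded.astype(int))
            starts = np.where(diff == 1)[0]
            ends = np.where(diff == -1)[0]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed_mask(path, chrom_lengths: dict) -> dict:
    mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    df = pd.read_csv(str(path), sep="\t", header=None, names=["chrom", "start", "end"])
    for row in df.itertuples(index=False):
        mask[row.chrom][row.start : row.end] = True
    return mask


def _vcf_header(chrom_lengths: dict, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    for kind, key, num, typ, desc in VCF_HEADER_LINES:
        header.add_meta(
            kind,
            items=[("ID", key), ("Number", num), ("Type", typ), ("Description", desc)],
        )
    header.add_sample(sample)
    return header


def write_vcf(records: list, chrom_lengths: dict, sample: str, path) -> None:
    """Write VariantRecords as a single-sample uncompressed VCF."""
    header = _vcf_header(chrom_lengths, sample)
    gt_codes = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            row = vcf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            row.info["QD"] = rec.qd
            row.info["FS"] = rec.fs
            row.info["MQ"] = rec.mq
            if rec.mq_rank_sum is not None:
                row.info["MQRankSum"] = rec.mq_rank_sum
            if rec.read_pos_rank_sum is not None:
                row.info["ReadPosRankSum"] = rec.read_pos_rank_sum
            row.info["DP"] = rec.dp
            row.samples[sample]["GT"] = gt_codes[rec.gt]
            row.samples[sample]["AD"] = (rec.dp - rec.adf - rec.adr, rec.adf + rec.adr)
            row.samples[sample]["DP"] = rec.dp
            row.samples[sample]["ADF"] = rec.adf
            row.samples[sample]["ADR"] = rec.adr
            vcf.write(row)


def read_vcf(path) -> list:
    """Read a single-sample VCF into VariantRecords, splitting multi-allelics."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for row in vcf:
            fmt = row.samples[sample]
            gt = fmt.get("GT")
            alts = row.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if gt is None or None in gt:
                    gt_label = "hom_ref"
                elif gt[0] == gt[1] == ai:
                    gt_label = "hom_alt"
                elif ai in gt:
                    gt_label = "het"
                elif gt[0] == gt[1] == 0:
                    gt_label = "hom_ref"
                else:
                    continue  # allele not carried by this sample
                out.append(
                    VariantRecord(
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=row.ref,
                        alt=alt,
                        qd=row.info.get("QD"),
                        fs=row.info.get("FS"),
                        mq=row.info.get("MQ"),
                        mq_rank_sum=row.info.get("MQRankSum"),
                        read_pos_rank_sum=row.info.get("ReadPosRankSum"),
                        dp=fmt.get("DP") if fmt.get("DP") is not None else row.info.get("DP", 0),
                        adf=fmt.get("ADF") or 0,
                        adr=fmt.get("ADR") or 0,
                        gt=gt_label,
                        sample_id=sample,
                    )
                )
    return out


def write_methylation_tsv(methylation: pd.DataFrame, path) -> None:
    df = methylation.copy()
    df["pos"] = df["pos"] + 1  # 1-based on disk
    df.to_csv(str(path), sep="\t", index=False)


def read_methylation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t")
    df["pos"] = df["pos"] - 1
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
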