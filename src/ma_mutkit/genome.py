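"""Synthetic reference genomes for mutation-accumulation experiments.

Builds a small multi-chromosome genome with a plant-like layout: protein-coding
genes (5'UTR - CDS - intron - CDS - 3'UTR), transposable-element intervals,
a callable-site mask covering most of the genome, and a per-cytosine
methylation landscape in the three plant contexts (CG, CHG, CHH).

All coordinates are 0-based half-open internally; emitted formats (GFF3, VCF)
are 1-based per their standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGT", "TGCA")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSpec:
    """Design of a synthetic genome.

    Fractions are of total genome length except ``cds_fraction_of_gene``,
    which is the portion of each gene body that is coding.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.36
    gene_fraction: float = 0.25
    te_fraction: float = 0.15
    cds_fraction_of_gene: float = 0.6
    callable_fraction: float = 0.969
    meth_prob: dict = field(
        default_factory=lambda: {"CG": 0.24, "CHG": 0.10, "CHH": 0.04}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length < 10_000:
            raise ValueError(
                "need >=1 chromosome of length >= 10000, got "
                f"{self.n_chromosomes} x {self.chrom_length}"
            )
        for name in (
            "gc_fraction",
            "gene_fraction",
            "te_fraction",
            "cds_fraction_of_gene",
            "callable_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gene_fraction + self.te_fraction > 0.9:
            raise ValueError("gene_fraction + te_fraction too large to place intervals")


@dataclass
class Reference:
    """A synthetic genome with annotation, callable mask, and methylation."""

    spec: GenomeSpec
    chromosomes: dict  # name -> sequence string
    features: pd.DataFrame  # chrom, start, end (0-based half-open), type, strand, gene_id
    callable_mask: dict  # name -> bool ndarray
    methylation: pd.DataFrame  # chrom, pos, strand, context, methylated, count_methylated, count_unmethylated

    @property
    def chrom_names(self):
        return list(self.chromosomes)

    def n_callable(self) -> int:
        return int(sum(m.sum() for m in self.callable_mask.values()))

    def base_composition(self) -> dict:
        """Callable-site counts of A:T and C:G bases (pairs counted per site)."""
        at = cg = 0
        for name, seq in self.chromosomes.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            mask = self.callable_mask[name]
            at += int(np.sum(mask & ((arr == b"A") | (arr == b"T"))))
            cg += int(np.sum(mask & ((arr == b"C") | (arr == b"G"))))
        return {"AT": at, "CG": cg}

    def te_intervals(self, chrom: str) -> np.ndarray:
        f = self.features
        sub = f[(f["chrom"] == chrom) & (f["type"] == "transposable_element")]
        return sub[["start", "end"]].to_numpy()

    def in_te(self, chrom: str, pos: int) -> bool:
        iv = self.te_intervals(chrom)
        return bool(np.any((iv[:, 0] <= pos) & (pos < iv[:, 1]))) if len(iv) else False


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _sample_codon(rng, gc: float) -> str:
    """A random non-stop codon with per-base GC probability ~gc."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        codon = "".join(BASES[rng.choice(4, size=3, p=p)])
        if codon not in STOP_CODONS:
            return codon


def _place_intervals(rng, length, sizes, occupied, min_gap=50):
    """Greedy non-overlapping placement; returns list of (start, end)."""
    placed = []
    for size in sizes:
        for _ in range(200):
            start = int(rng.integers(min_gap, length - size - min_gap))
            end = start + size
            if all(end + min_gap <= s or start >= e + min_gap for s, e in occupied):
                occupied.append((start, end))
                placed.append((start, end))
                break
    return placed


def _gene_structure(start, end, cds_fraction, rng):
    """Split a gene interval into UTR5, CDS1, intron, CDS2, UTR3 segments."""
    length = end - start
    cds_total = int(length * cds_fraction) // 3 * 3
    cds_total = max(cds_total, 30)
    rest = length - cds_total
    utr5 = max(rest // 3, 10)
    utr3 = max(rest // 3, 10)
    intron = length - cds_total - utr5 - utr3
    if intron < 20:
        intron = 20
        cds_total = (length - utr5 - utr3 - intron) // 3 * 3
    cds1 = int(rng.integers(1, cds_total // 3)) * 3
    cds2 = cds_total - cds1
    s = start
    segs = []
    for name, ln in (
        ("five_prime_UTR", utr5),
        ("CDS", cds1),
        ("intron", intron),
        ("CDS", cds2),
        ("three_prime_UTR", utr3),
    ):
        segs.append((name, s, s + ln))
        s += ln
    return segs


def _cytosine_contexts(seq_arr: np.ndarray):
    """Contexts for forward-strand C and reverse-strand C (genomic G).

    Returns (positions, strands, contexts) over the whole chromosome,
    excluding the last/first 2 bp where the context is undefined.
    """
    n = len(seq_arr)
    is_c = seq_arr == 1  # ACGT -> 0123
    is_g = seq_arr == 2
    pos_c = np.where(is_c[: n - 2])[0]
    nxt1 = seq_arr[pos_c + 1]
    nxt2 = seq_arr[pos_c + 2]
    ctx_c = np.where(nxt1 == 2, "CG", np.where(nxt2 == 2, "CHG", "CHH"))
    pos_g = np.where(is_g[2:])[0] + 2
    prv1 = seq_arr[pos_g - 1]
    prv2 = seq_arr[pos_g - 2]
    ctx_g = np.where(prv1 == 1, "CG", np.where(prv2 == 1, "CHG", "CHH"))
    positions = np.concatenate([pos_c, pos_g])
    strands = np.concatenate([np.full(len(pos_c), "+"), np.full(len(pos_g), "-")])
    contexts = np.concatenate([ctx_c, ctx_g])
    order = np.argsort(positions, kind="stable")
    return positions[order], strands[order], contexts[order]


def generate_reference(spec: GenomeSpec) -> Reference:
    """Generate a deterministic synthetic reference from a GenomeSpec.

    Gene CDS regions are rewritten to valid open reading frames
    (ATG ... non-stop codons ... TAA) so coding-effect annotation and Ka/Ks
    site counting operate on translatable sequence.
    """
    rng = np.random.default_rng(spec.seed)
    chromosomes = {}
    feat_rows = []
    callable_mask = {}
    meth_frames = []

    for ci in range(spec.n_chromosomes):
        name = f"chr{ci + 1}"
        arr = _random_sequence(rng, spec.chrom_length, spec.gc_fraction)

        # genes
        occupied: list = []
        gene_bp = int(spec.chrom_length * spec.gene_fraction)
        sizes = []
        while sum(sizes) < gene_bp:
            sizes.append(int(rng.integers(900, 2400)))
        genes = _place_intervals(rng, spec.chrom_length, sizes, occupied)
        for gi, (gs, ge) in enumerate(genes):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{name}_g{gi + 1}"
            feat_rows.append((name, gs, ge, "gene", strand, gene_id))
            segs = _gene_structure(gs, ge, spec.cds_fraction_of_gene, rng)
            # rewrite CDS codons into a valid ORF (in transcription order)
            cds_segs = [(s, e) for t, s, e in segs if t == "CDS"]
            cds_len = sum(e - s for s, e in cds_segs)
            codons = ["ATG"]
            codons += [_sample_codon(rng, spec.gc_fraction) for _ in range(cds_len // 3 - 2)]
            codons.append("TAA")
            cds_seq = "".join(codons)
            if strand == "-":
                cds_seq = revcomp(cds_seq)
                # on minus strand the genomic order of CDS bases is reversed
            offset = 0
            for s, e in cds_segs:
                piece = cds_seq[offset : offset + (e - s)]
                arr[s:e] = [("ACGT").index(b) for b in piece]
                offset += e - s
            for t, s, e in segs:
                if t == "intron":
                    continue  # introns are implicit (gene minus emitted parts)
                if strand == "-" and t.endswith("UTR"):
                    # genomic layout is transcription order reversed
                    t = "three_prime_UTR" if t == "five_prime_UTR" else "five_prime_UTR"
                feat_rows.append((name, s, e, t, strand, gene_id))

        # transposable elements, disjoint from genes
        te_bp = int(spec.chrom_length * spec.te_fraction)
        sizes = []
        while sum(sizes) < te_bp:
            sizes.append(int(rng.integers(400, 3000)))
        tes = _place_intervals(rng, spec.chrom_length, sizes, occupied)
        for ti, (ts, te_) in enumerate(tes):
            feat_rows.append((name, ts, te_, "transposable_element", "+", f"{name}_te{ti + 1}"))

        seq = "".join(BASES[arr])
        chromosomes[name] = seq

        # callable mask: drop random blocks until uncallable fraction reached
        mask = np.ones(spec.chrom_length, dtype=bool)
        target_uncallable = int(round(spec.chrom_length * (1 - spec.callable_fraction)))
        while mask.size - mask.sum() < target_uncallable:
            blk = int(rng.integers(100, 1000))
            start = int(rng.integers(0, spec.chrom_length - blk))
            mask[start : start + blk] = False
        callable_mask[name] = mask

        # methylation landscape
        pos, strand_arr, ctx = _cytosine_contexts(arr)
        p = np.vectorize(spec.meth_prob.get)(ctx) if len(ctx) else np.array([])
        methylated = rng.random(len(pos)) < p
        total = rng.poisson(20, size=len(pos)) + 1
        level = np.where(methylated, 0.85, 0.02)
        n_meth = rng.binomial(total, level)
        meth_frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "strand": strand_arr,
                    "context": ctx,
                    "methylated": methylated,
                    "count_methylated": n_meth,
                    "count_unmethylated": total - n_meth,
                }
            )
        )

    features = pd.DataFrame(
        feat_rows, columns=["chrom", "start", "end", "type", "strand", "gene_id"]
    )
    methylation = pd.concat(meth_frames, ignore_index=True)
    return Reference(spec, chromosomes, features, callable_mask, methylation)
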