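"""Forward simulation of mutation accumulation and noisy variant-call emission.

Two experimental designs are emulated:

* ``line`` mode — independent single-seed-descent lineages; each lineage
  accumulates Poisson(rate x callable sites x generations) mutations, all
  private to that lineage (mutations fix by selfing and are emitted as
  homozygous).
* ``population`` mode — a selfing population of constant size; each offspring
  draws one parent at random from the previous generation and inherits its
  mutations, so a mutation arising in generation k can be shared by several
  sampled final-generation individuals.

Substitution identities are drawn from the treatment's six-class spectrum
weights; the mutated site is then drawn from callable sites with a compatible
focal base, weighted by the methylation and transposable-element mutability
multipliers. Under this scheme the realized class frequencies are unbiased
estimates of the spectrum weights irrespective of genome base composition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .genome import Reference
from .records import SPECTRUM_CLASSES, VariantRecord

_CLASS_TO_ALT = {
    # focal base -> alt base for each six-class label
    "C:G>T:A": {"C": "T", "G": "A"},
    "C:G>A:T": {"C": "A", "G": "T"},
    "C:G>G:C": {"C": "G", "G": "C"},
    "A:T>G:C": {"A": "G", "T": "C"},
    "A:T>T:A": {"A": "T", "T": "A"},
    "A:T>C:G": {"A": "C", "T": "G"},
}


@dataclass(frozen=True)
class TreatmentSpec:
    """Design of one treatment arm of an MA experiment."""

    label: str = "Control"
    generations: int = 10
    n_lineages: int = 5
    mode: str = "line"  # line | population
    population_size: int = 35
    snv_rate: float = 5.0e-9
    indel_rate: float = 1.5e-9
    spectrum_weights: tuple = (0.45, 0.11, 0.08, 0.16, 0.12, 0.08)
    del_fraction: float = 0.75
    indel_length_pmf: tuple = (0.6, 0.25, 0.15)  # lengths 1..L
    meth_multiplier: float = 1.0
    te_multiplier: float = 1.0

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mode not in ("line", "population"):
            raise ValueError(f"unknown mode {self.mode}")
        if self.snv_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        w = np.asarray(self.spectrum_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum_weights must be 6 non-negative weights summing to 1")
        p = np.asarray(self.indel_length_pmf, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("indel_length_pmf must sum to 1")
        if not 0 <= self.del_fraction <= 1:
            raise ValueError("del_fraction must be in [0,1]")


@dataclass(frozen=True)
class SimulatedMutation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mclass: str  # six-class label for SNVs, 'insertion'/'deletion' otherwise
    generation: int
    shared: bool = False

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


class _SiteSampler:
    """Weighted sampling of mutable callable sites, split by focal base pair."""

    def __init__(self, reference: Reference, treatment: TreatmentSpec):
        chroms, positions, weights, is_cg = [], [], [], []
        meth_by_chrom = {}
        m = reference.methylation
        meth = m[m["methylated"]]
        for chrom, grp in meth.groupby("chrom"):
            meth_by_chrom[chrom] = np.unique(grp["pos"].to_numpy())
        for ci, (chrom, seq) in enumerate(reference.chromosomes.items()):
            arr = np.frombuffer(seq.encode(), dtype="S1")
            mask = reference.callable_mask[chrom].copy()
            mask[:2] = mask[-2:] = False  # keep trinucleotide context defined
            pos = np.where(mask)[0]
            base = arr[pos]
            cg = (base == b"C") | (base == b"G")
            w = np.ones(len(pos))
            meth_pos = meth_by_chrom.get(chrom, np.array([], dtype=int))
            if treatment.meth_multiplier != 1.0 and len(meth_pos):
                is_meth = np.isin(pos, meth_pos)
                w[is_meth] *= treatment.meth_multiplier
            if treatment.te_multiplier != 1.0:
                te = np.zeros(len(seq), dtype=bool)
                for s, e in reference.te_intervals(chrom):
                    te[s:e] = True
                w[te[pos]] *= treatment.te_multiplier
            chroms.append(np.full(len(pos), ci))
            positions.append(pos)
            weights.append(w)
            is_cg.append(cg)
        self.chrom_names = list(reference.chromosomes)
        self.chrom_idx = np.concatenate(chroms)
        self.positions = np.concatenate(positions)
        self.weights = np.concatenate(weights)
        self.is_cg = np.concatenate(is_cg)
        self.logw = np.log(self.weights)
        self.cg_sites = np.where(self.is_cg)[0]
        self.at_sites = np.where(~self.is_cg)[0]

    def draw(self, rng, subset: np.ndarray, k: int) -> np.ndarray:
        """Weighted sample without replacement via the Gumbel top-k trick."""
        if k == 0:
            return np.array([], dtype=int)
        if k > len(subset):
            raise ValueError("more draws requested than available sites")
        keys = self.logw[subset] + rng.gumbel(size=len(subset))
        return subset[np.argpartition(-keys, k - 1)[:k]]


def _lineage_rng(seed: int, *ids) -> np.random.Generator:
    """Stable per-lineage substream: adding lineages never perturbs others."""
    words = [zlib.crc32(str(i).encode()) for i in ids]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + words))


def _make_mutations(reference, treatment, sampler, rng, n_snv, n_indel, generations):
    """Draw n_snv + n_indel concrete mutations (positions pairwise distinct)."""
    muts = []
    used = set()

    if n_snv:
        class_counts = rng.multinomial(n_snv, np.asarray(treatment.spectrum_weights))
        # sites are drawn jointly per focal group (CG classes share the CG
        # site pool), so SNV positions are distinct by construction
        for group, subset in (("C:G", sampler.cg_sites), ("A:T", sampler.at_sites)):
            cls_ids = [i for i, c in enumerate(SPECTRUM_CLASSES) if c.startswith(group)]
            k = int(sum(class_counts[i] for i in cls_ids))
            if k == 0:
                continue
            if k > len(subset):
                raise ValueError(
                    f"spectrum weight on {group} classes but only {len(subset)} "
                    f"compatible callable sites for {k} draws"
                )
            idx = sampler.draw(rng, subset, k)
            labels = np.repeat(
                [SPECTRUM_CLASSES[i] for i in cls_ids],
                [class_counts[i] for i in cls_ids],
            )
            rng.shuffle(idx)
            gens = rng.integers(1, generations + 1, size=k)
            for i, label, gen in zip(idx, labels, gens):
                chrom = sampler.chrom_names[sampler.chrom_idx[i]]
                pos = int(sampler.positions[i])
                used.add((chrom, pos))
                ref_base = reference.chromosomes[chrom][pos]
                alt = _CLASS_TO_ALT[label][ref_base]
                muts.append(
                    SimulatedMutation(chrom, pos + 1, ref_base, alt, label, int(gen))
                )

    for _ in range(n_indel):
        length = 1 + int(rng.choice(len(treatment.indel_length_pmf), p=np.asarray(treatment.indel_length_pmf)))
        is_del = rng.random() < treatment.del_fraction
        all_sites = np.arange(len(sampler.positions))
        for _ in range(50):
            idx = int(sampler.draw(rng, all_sites, 1)[0])
            chrom = sampler.chrom_names[sampler.chrom_idx[idx]]
            pos = int(sampler.positions[idx])
            if all((chrom, p) not in used for p in range(pos - 3, pos + length + 1)):
                break
        for p in range(pos - 3, pos + length + 1):
            used.add((chrom, p))
        seq = reference.chromosomes[chrom]
        if is_del:
            if pos + length + 1 > len(seq):
                pos = len(seq) - length - 3
            ref = seq[pos : pos + length + 1]
            alt = ref[0]
            mclass = "deletion"
        else:
            ref = seq[pos]
            alt = ref + "".join(
                "ACGT"[b] for b in rng.integers(0, 4, size=length)
            )
            mclass = "insertion"
        muts.append(
            SimulatedMutation(chrom, pos + 1, ref, alt, mclass, int(rng.integers(1, generations + 1)))
        )
    return muts


def simulate_ma(reference: Reference, treatment: TreatmentSpec, seed: int) -> dict:
    """Simulate one treatment arm; returns {sample_id: [SimulatedMutation, ...]}."""
    sampler = _SiteSampler(reference, treatment)
    b = reference.n_callable()
    g = treatment.generations
    truth = {}

    if treatment.mode == "line":
        for li in range(treatment.n_lineages):
            rng = _lineage_rng(seed, treatment.label, li)
            n_snv = rng.poisson(treatment.snv_rate * b * g)
            n_indel = rng.poisson(treatment.indel_rate * b * g)
            sample_id = f"{treatment.label}_L{li + 1}"
            truth[sample_id] = _make_mutations(
                reference, treatment, sampler, rng, n_snv, n_indel, g
            )
        return truth

    # population mode: selfing, one random parent per offspring each generation
    rng = _lineage_rng(seed, treatment.label, "population")
    n = treatment.population_size
    individuals = [[] for _ in range(n)]  # mutation lists
    for gen in range(1, g + 1):
        parents = rng.integers(0, n, size=n)
        nxt = []
        for child in range(n):
            inherited = list(individuals[parents[child]])
            n_snv = rng.poisson(treatment.snv_rate * b)
            n_indel = rng.poisson(treatment.indel_rate * b)
            if n_snv or n_indel:
                new = _make_mutations(
                    reference, treatment, sampler, rng, n_snv, n_indel, g
                )
                new = [
                    SimulatedMutation(m.chrom, m.pos, m.ref, m.alt, m.mclass, gen)
                    for m in new
                ]
                inherited.extend(new)
            nxt.append(inherited)
        individuals = nxt
    sampled = rng.choice(n, size=treatment.n_lineages, replace=False)
    # count carriers among sampled individuals to set the shared flag
    carrier_counts: dict = {}
    for si in sampled:
        seen = set()
        for m in individuals[si]:
            if m.key not in seen:
                carrier_counts[m.key] = carrier_counts.get(m.key, 0) + 1
                seen.add(m.key)
    for k, si in enumerate(sampled):
        sample_id = f"{treatment.label}_P{k + 1}"
        dedup: dict = {}
        for m in individuals[si]:
            if m.key in dedup:
                continue
            dedup[m.key] = SimulatedMutation(
                m.chrom, m.pos, m.ref, m.alt, m.mclass, m.generation,
                shared=carrier_counts[m.key] >= 2,
            )
        # drop position collisions (two distinct mutations at one site)
        by_pos: dict = {}
        for m in dedup.values():
            by_pos.setdefault((m.chrom, m.pos), m)
        truth[sample_id] = list(by_pos.values())
    return truth


@dataclass(frozen=True)
class NoiseConfig:
    """Per-sample decoy counts, each removable by exactly one filter."""

    n_low_dp: int = 0
    n_single_strand: int = 0
    n_near_indel: int = 0
    n_indel_pair: int = 0
    n_het: int = 0
    n_in_background: int = 0
    n_background_het: int = 0

    def total(self):
        return (
            self.n_low_dp + self.n_single_strand + self.n_near_indel
            + 2 * self.n_indel_pair + self.n_het + self.n_in_background
            + self.n_background_het
        )


_PASSING = dict(qd=25.0, fs=2.0, mq=60.0, mq_rank_sum=None, read_pos_rank_sum=None, dp=40)


def _passing_record(chrom, pos, ref, alt, sample_id, rng, gt="hom_alt", dp=None,
                    adf=None, adr=None):
    dp = int(dp if dp is not None else 30 + rng.integers(0, 21))
    if gt == "hom_alt":
        total_alt = dp
    elif gt == "het":
        total_alt = dp // 2
    else:
        total_alt = 0
    if adf is None:
        adf = total_alt // 2
    if adr is None:
        adr = total_alt - adf
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        qd=_PASSING["qd"], fs=_PASSING["fs"], mq=_PASSING["mq"],
        mq_rank_sum=None, read_pos_rank_sum=None,
        dp=dp, adf=int(adf), adr=int(adr), gt=gt, sample_id=sample_id,
    )


def _background_ref_record(chrom, pos, ref, rng):
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref[0]]
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref[0], alt=alt,
        qd=None, fs=None, mq=60.0, mq_rank_sum=None, read_pos_rank_sum=None,
        dp=int(25 + rng.integers(0, 16)), adf=0, adr=0, gt="hom_ref",
        sample_id="background",
    )


def emit_variant_calls(
    reference: Reference,
    truth: dict,
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    max_retries: int = 1000,
):
    """Turn simulated truth into per-sample call tables plus a background table.

    Returns (sample_records, background_records, decoy_table) where
    sample_records maps sample_id -> [VariantRecord, ...], background_records
    is a single list covering every candidate site, and decoy_table is a list
    of (sample_id, chrom, pos, category) rows (the side-channel truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    sample_records = {}
    background: dict = {}
    decoys = []

    # occupied positions per chromosome across samples, padded for spacing
    occupied: dict = {}

    def reserve(chrom, lo, hi):
        occ = occupied.setdefault(chrom, set())
        occ.update(range(lo, hi + 1))

    def is_free(chrom, lo, hi):
        occ = occupied.setdefault(chrom, set())
        return not any(p in occ for p in range(lo, hi + 1))

    pad = 30  # decoys and truth kept this far apart so filters never interact

    for sample_id, muts in truth.items():
        for m in muts:
            reserve(m.chrom, m.pos - pad, m.pos + len(m.ref) + pad)

    def free_site(min_margin=5):
        for _ in range(max_retries):
            chrom = reference.chrom_names[rng.integers(0, len(reference.chrom_names))]
            mask = reference.callable_mask[chrom]
            pos0 = int(rng.integers(min_margin, len(mask) - min_margin))
            if mask[pos0] and is_free(chrom, pos0 - pad, pos0 + pad):
                return chrom, pos0
        raise RuntimeError("could not place decoy after bounded retries")

    def add_background_ref(chrom, pos1):
        if (chrom, pos1) not in background:
            ref = reference.chromosomes[chrom][pos1 - 1]
            background[(chrom, pos1)] = _background_ref_record(chrom, pos1, ref, rng)

    for sample_id, muts in truth.items():
        recs = []
        for m in muts:
            recs.append(_passing_record(m.chrom, m.pos, m.ref, m.alt, sample_id, rng))
            add_background_ref(m.chrom, m.pos)

        def snv_alleles(chrom, pos0):
            ref = reference.chromosomes[chrom][pos0]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            return ref, alt

        for _ in range(noise.n_low_dp):
            chrom, pos0 = free_site()
            reserve(chrom, pos0 - pad, pos0 + pad)
            ref, alt = snv_alleles(chrom, pos0)
            dp = int(rng.integers(1, 8))
            recs.append(
                _passing_record(chrom, pos0 + 1, ref, alt, sample_id, rng, dp=dp,
                                adf=dp // 2, adr=dp - dp // 2)
            )
            add_background_ref(chrom, pos0 + 1)
            decoys.append((sample_id, chrom, pos0 + 1, "low_dp"))

        for _ in range(noise.n_single_strand):
            chrom, pos0 = free_site()
            reserve(chrom, pos0 - pad, pos0 + pad)
            ref, alt = snv_alleles(chrom, pos0)
            rec = _passing_record(chrom, pos0 + 1, ref, alt, sample_id, rng)
            rec = VariantRecord(**{**rec.__dict__, "adf": rec.adf + rec.adr, "adr": 0})
            recs.append(rec)
            add_background_ref(chrom, pos0 + 1)
            decoys.append((sample_id, chrom, pos0 + 1, "single_strand"))

        for _ in range(noise.n_near_indel):
            # an SNV within <10 bp of an indel; the companion indel is itself a
            # background variant so neither survives
            chrom, pos0 = free_site(min_margin=15)
            reserve(chrom, pos0 - pad, pos0 + pad + 12)
            ref, alt = snv_alleles(chrom, pos0)
            recs.append(_passing_record(chrom, pos0 + 1, ref, alt, sample_id, rng))
            add_background_ref(chrom, pos0 + 1)
            ind_pos0 = pos0 + int(rng.integers(3, 9))
            iref = reference.chromosomes[chrom][ind_pos0 : ind_pos0 + 2]
            irec = _passing_record(chrom, ind_pos0 + 1, iref, iref[0], sample_id, rng)
            recs.append(irec)
            background[(chrom, ind_pos0 + 1)] = VariantRecord(
                **{**irec.__dict__, "sample_id": "background"}
            )
            decoys.append((sample_id, chrom, pos0 + 1, "near_indel_snv"))
            decoys.append((sample_id, chrom, ind_pos0 + 1, "near_indel_companion"))

        for _ in range(noise.n_indel_pair):
            chrom, pos0 = free_site(min_margin=40)
            reserve(chrom, pos0 - pad, pos0 + pad + 40)
            gap = int(rng.integers(5, 20))  # bases between spans, <= 20
            for k, p0 in enumerate((pos0, pos0 + 1 + gap + 1)):
                iref = reference.chromosomes[chrom][p0 : p0 + 2]
                recs.append(_passing_record(chrom, p0 + 1, iref, iref[0], sample_id, rng))
                add_background_ref(chrom, p0 + 1)
                decoys.append((sample_id, chrom, p0 + 1, "indel_pair"))

        for _ in range(noise.n_het):
            chrom, pos0 = free_site()
            reserve(chrom, pos0 - pad, pos0 + pad)
            ref, alt = snv_alleles(chrom, pos0)
            recs.append(_passing_record(chrom, pos0 + 1, ref, alt, sample_id, rng, gt="het"))
            add_background_ref(chrom, pos0 + 1)
            decoys.append((sample_id, chrom, pos0 + 1, "heterozygous"))

        for _ in range(noise.n_in_background):
            chrom, pos0 = free_site()
            reserve(chrom, pos0 - pad, pos0 + pad)
            ref, alt = snv_alleles(chrom, pos0)
            rec = _passing_record(chrom, pos0 + 1, ref, alt, sample_id, rng)
            recs.append(rec)
            background[(chrom, pos0 + 1)] = VariantRecord(
                **{**rec.__dict__, "sample_id": "background"}
            )
            decoys.append((sample_id, chrom, pos0 + 1, "in_background"))

        for _ in range(noise.n_background_het):
            chrom, pos0 = free_site()
            reserve(chrom, pos0 - pad, pos0 + pad)
            ref, alt = snv_alleles(chrom, pos0)
            recs.append(_passing_record(chrom, pos0 + 1, ref, alt, sample_id, rng))
            bg = _passing_record(chrom, pos0 + 1, ref, alt, "background", rng, gt="het")
            background[(chrom, pos0 + 1)] = bg
            decoys.append((sample_id, chrom, pos0 + 1, "background_het"))

        sample_records[sample_id] = recs

    return sample_records, list(background.values()), decoys


def plant_reference_snvs(reference: Reference, n_per_genome: int, n_genomes: int, seed: int):
    """Plant substitutions into copies of the reference, evenly per chromosome.

    Returns (genome_copies, planted) where genome_copies is a list of
    {chrom: sequence} dicts and planted a list of per-genome
    [(chrom, pos 1-based, ref, alt), ...] lists.
    """
    n_chrom = len(reference.chrom_names)
    if n_per_genome % max(n_chrom, 1) != 0:
        raise ValueError(
            f"n_per_genome={n_per_genome} not divisible by {n_chrom} chromosomes"
        )
    per_chrom = n_per_genome // n_chrom
    copies, planted = [], []
    for gi in range(n_genomes):
        rng = _lineage_rng(seed, "plant", gi)
        seqs = {}
        muts = []
        for chrom in reference.chrom_names:
            seq = list(reference.chromosomes[chrom])
            mask = reference.callable_mask[chrom]
            sites = np.where(mask)[0]
            if per_chrom > len(sites):
                raise ValueError("per-chromosome quota exceeds callable sites")
            chosen = rng.choice(sites, size=per_chrom, replace=False)
            for pos0 in sorted(int(p) for p in chosen):
                ref = seq[pos0]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                seq[pos0] = alt
                muts.append((chrom, pos0 + 1, ref, alt))
            seqs[chrom] = "".join(seq)
        copies.append(seqs)
        planted.append(muts)
    return copies, planted
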