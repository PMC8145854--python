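"""Mutation frequencies, per-site per-generation rates, spectra, and Ts/Tv.

Definitions:

* mutation frequency (per genome per generation): m = n / g
* mutation rate (per site per generation): mu = n / (g * b), with b the
  number of accessible (callable) sites of that lineage
* conditional six-class rates: class count divided by the number of callable
  sites capable of producing that class (A:T or C:G sites), times g and the
  number of lineages
* treatment summaries are means +/- SEM over per-lineage values; treatment
  comparisons use a two-tailed two-sample Student's t test (Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import SPECTRUM_CLASSES, MutationCall, TRANSITIONS


def mutation_frequency(n: int, g: int) -> float:
    """Per-genome per-generation mutation frequency m = n/g."""
    if g < 1:
        raise ValueError("generations must be >= 1")
    return n / g


def treatment_mean_frequency(ns, g: int) -> float:
    """Mean of per-sample frequencies, sum(m_i)/n_samples."""
    return float(np.mean([mutation_frequency(n, g) for n in ns]))


def mutation_rate(n: int, g: int, b: int) -> float:
    """Per-site per-generation rate mu = n/(g*b)."""
    if g < 1:
        raise ValueError("generations must be >= 1")
    if b <= 0:
        raise ValueError("accessible sites b must be > 0")
    return n / (g * b)


@dataclass
class RateEstimate:
    per_lineage_values: list
    n: int
    g: int
    b: list

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_lineage_values))

    @property
    def sem(self) -> float:
        v = self.per_lineage_values
        if len(v) < 2:
            return float("nan")
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    @property
    def pooled(self) -> float:
        """Pooled alternative: total n over total g*b."""
        return self.n / (self.g * float(np.sum(self.b)))

    def to_dict(self):
        return {
            "mean": self.mean,
            "sem": self.sem,
            "pooled": self.pooled,
            "n": self.n,
            "g": self.g,
            "per_lineage": list(self.per_lineage_values),
        }


def treatment_summary(counts, b, g: int) -> RateEstimate:
    """Per-lineage rates and their mean/SEM for one treatment arm."""
    counts = list(counts)
    b = list(b)
    if len(counts) != len(b):
        raise ValueError(f"{len(counts)} lineage counts but {len(b)} site totals")
    per = [mutation_rate(n, g, bi) for n, bi in zip(counts, b)]
    return RateEstimate(per_lineage_values=per, n=int(sum(counts)), g=g, b=b)


def compare_treatments(a: RateEstimate, b: RateEstimate, welch: bool = False):
    """Two-tailed two-sample t test on per-lineage rates. Returns (t, p)."""
    t, p = stats.ttest_ind(
        a.per_lineage_values, b.per_lineage_values, equal_var=not welch
    )
    return float(t), float(p)


def conditional_spectrum(calls, composition: dict, g: int, n_lineages: int) -> pd.DataFrame:
    """Six-class conditional rates given callable A:T / C:G site counts.

    ``composition`` maps 'AT' and 'CG' to the number of callable sites with
    that focal base pair.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for call in calls:
        if call.mtype != "SNV":
            continue
        counts[call.spectrum_class] += 1
    rows = []
    for cls in SPECTRUM_CLASSES:
        avail = composition["CG"] if cls.startswith("C:G") else composition["AT"]
        n = counts[cls]
        if avail == 0 and n > 0:
            raise ValueError(f"{n} {cls} mutations but zero available sites")
        rate = n / (avail * g * n_lineages) if avail else 0.0
        rows.append({"class": cls, "count": n, "available_sites": avail, "rate": rate})
    return pd.DataFrame(rows)


@dataclass
class TsTvSummary:
    ts_count: int
    tv_count: int
    g: int
    n_lineages: int

    @property
    def ts_frequency(self) -> float:
        return self.ts_count / (self.g * self.n_lineages)

    @property
    def tv_frequency(self) -> float:
        return self.tv_count / (self.g * self.n_lineages)

    @property
    def ratio(self):
        """Ts/Tv, or None when no transversions were observed."""
        if self.tv_count == 0:
            return None
        return self.ts_count / self.tv_count

    def to_dict(self):
        return {
            "ts_count": self.ts_count,
            "tv_count": self.tv_count,
            "ts_frequency": self.ts_frequency,
            "tv_frequency": self.tv_frequency,
            "ratio": self.ratio,
        }


def ts_tv_summary(calls, g: int, n_lineages: int, unique: bool = False) -> TsTvSummary:
    """Transition/transversion counts over SNV calls.

    With ``unique=True`` mutations shared between samples (same chrom, pos,
    ref, alt) are counted once.
    """
    snvs = [c for c in calls if c.mtype == "SNV"]
    if unique:
        seen = {}
        for c in snvs:
            seen.setdefault(c.key, c)
        snvs = list(seen.values())
    ts = sum(1 for c in snvs if (c.ref, c.alt) in TRANSITIONS)
    return TsTvSummary(ts_count=ts, tv_count=len(snvs) - ts, g=g, n_lineages=n_lineages)


def indel_profile(calls, g: int, b: int) -> dict:
    """Length histogram and del/ins counts and rates for indel calls."""
    indels = []
    for c in calls:
        if c.mtype == "SNV":
            raise ValueError("indel_profile expects indel calls only")
        indels.append(c)
    hist: dict = {}
    n_del = n_ins = 0
    short = 0
    for c in indels:
        signed = -c.length if c.mtype == "deletion" else c.length
        hist[signed] = hist.get(signed, 0) + 1
        if c.mtype == "deletion":
            n_del += 1
        else:
            n_ins += 1
        if 1 <= c.length <= 3:
            short += 1
    return {
        "length_histogram": dict(sorted(hist.items())),
        "n_deletions": n_del,
        "n_insertions": n_ins,
        "deletion_rate": mutation_rate(n_del, g, b),
        "insertion_rate": mutation_rate(n_ins, g, b),
        "fraction_length_1_3": short / len(indels) if indels else float("nan"),
    }
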