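"""Local-context mutation bias: trinucleotide rates, GC windows, gene density.

Trinucleotide contexts are collapsed by reverse complement to 32 classes
(16 flanking combinations x focal A-or-T, 16 x focal C-or-G); a context and
its reverse complement contribute to the same class (e.g. the tAt class pools
tAt and aTa sites). Genomic denominators count every position once on the
forward strand.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .genome import Reference, revcomp


def collapse_trinucleotide(tri: str) -> str:
    """Representative with focal base A or C (reverse complement otherwise)."""
    if tri[1] in "AC":
        return tri
    return revcomp(tri)


def context_label(tri: str) -> str:
    """Display form: flanks lowercase, focal uppercase (e.g. tAt)."""
    t = collapse_trinucleotide(tri)
    return t[0].lower() + t[1] + t[2].lower()


ALL_CONTEXTS = sorted(
    {collapse_trinucleotide("".join(t)) for t in product("ACGT", repeat=3)}
)


def genome_context_counts(reference: Reference) -> dict:
    """Callable-site counts of each collapsed trinucleotide context."""
    counts = {c: 0 for c in ALL_CONTEXTS}
    for chrom, seq in reference.chromosomes.items():
        mask = reference.callable_mask[chrom]
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        n = len(arr)
        tri = np.char.add(np.char.add(arr[: n - 2], arr[1 : n - 1]), arr[2:])
        ok = mask[1 : n - 1]
        vals, cnts = np.unique(tri[ok], return_counts=True)
        for v, c in zip(vals, cnts):
            counts[collapse_trinucleotide(str(v))] += int(c)
    return counts


def trinucleotide_rates(calls, reference: Reference, g: int, n_lineages: int):
    """Per-context SNV mutation rates; calls at contig ends are excluded.

    Returns (table, n_excluded): table has one row per collapsed context with
    count, available sites, and rate = count / (sites * g * n_lineages).
    """
    site_counts = genome_context_counts(reference)
    counts = {c: 0 for c in ALL_CONTEXTS}
    excluded = 0
    for call in calls:
        if call.mtype != "SNV":
            continue
        seq = reference.chromosomes[call.chrom]
        pos0 = call.pos - 1
        if pos0 < 1 or pos0 >= len(seq) - 1:
            excluded += 1
            continue
        tri = seq[pos0 - 1 : pos0 + 2]
        counts[collapse_trinucleotide(tri)] += 1
    rows = []
    for ctx in ALL_CONTEXTS:
        avail = site_counts[ctx]
        rate = counts[ctx] / (avail * g * n_lineages) if avail else 0.0
        rows.append(
            {
                "context": context_label(ctx),
                "focal": "AT" if ctx[1] == "A" else "CG",
                "count": counts[ctx],
                "available_sites": avail,
                "rate": rate,
            }
        )
    return pd.DataFrame(rows), excluded


def g_test_uniformity(counts, expected_proportions=None):
    """Log-likelihood-ratio goodness-of-fit test, G = 2 sum O ln(O/E).

    Zero-count cells contribute 0 (the 0*ln 0 limit). Chi-square reference
    with df = k - 1. Returns (G, p).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.sum() == 0:
        raise ValueError("all-zero counts")
    if expected_proportions is None:
        expected_proportions = np.full(len(obs), 1.0 / len(obs))
    exp_p = np.asarray(expected_proportions, dtype=float)
    if abs(exp_p.sum() - 1.0) > 1e-8:
        raise ValueError("expected proportions must sum to 1")
    exp = exp_p * obs.sum()
    g_stat, p = stats.power_divergence(obs, exp, lambda_="log-likelihood")
    return float(g_stat), float(p)


def z_test_context(focal_count, focal_sites, other_count, other_sites):
    """Two-proportion two-tailed Z test of per-site mutation proportions."""
    if focal_sites <= 0 or other_sites <= 0:
        raise ValueError("site exposures must be positive")
    z, p = proportions_ztest(
        np.array([focal_count, other_count]),
        np.array([focal_sites, other_sites]),
        alternative="two-sided",
    )
    return float(z), float(p)


def elevated_contexts(table: pd.DataFrame, focal: str, g: int, n_lineages: int,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Z test of each context against the pooled remaining same-focal contexts."""
    sub = table[table["focal"] == focal]
    rows = []
    for _, row in sub.iterrows():
        rest = sub[sub["context"] != row["context"]]
        oc, os_ = int(rest["count"].sum()), int(rest["available_sites"].sum())
        fs = int(row["available_sites"]) * g * n_lineages
        os_total = os_ * g * n_lineages
        z, p = z_test_context(int(row["count"]), fs, oc, os_total)
        rows.append({"context": row["context"], "z": z, "p": p, "elevated": z > 0 and p < alpha})
    return pd.DataFrame(rows)


def gc_window_rates(calls, reference: Reference, g: int, window: int = 1000,
                    gc_interval: float = 0.005) -> pd.DataFrame:
    """Mutation rate as a function of window GC content.

    Chromosomes are tiled into non-overlapping windows of ``window`` bp; each
    window is assigned a GC bin of width ``gc_interval``; the per-bin rate is
    mu = n / (m * g * window) with m the number of windows in the bin and n
    the mutations falling in them.
    """
    if window <= 0 or gc_interval <= 0:
        raise ValueError("window and gc_interval must be positive")
    win_rows = []
    for chrom, seq in reference.chromosomes.items():
        if window > len(seq):
            raise ValueError(f"window {window} exceeds {chrom} length {len(seq)}")
        arr = np.frombuffer(seq.encode(), dtype="S1")
        gc = (arr == b"G") | (arr == b"C")
        n_win = len(seq) // window
        for wi in range(n_win):
            frac = gc[wi * window : (wi + 1) * window].mean()
            win_rows.append((chrom, wi * window, (wi + 1) * window, float(frac)))
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end", "gc"])
    windows["bin"] = (windows["gc"] / gc_interval).astype(int)

    counts = np.zeros(len(windows), dtype=int)
    index = {(r.chrom, r.start // window): i for i, r in enumerate(windows.itertuples(index=False))}
    for call in calls:
        key = (call.chrom, (call.pos - 1) // window)
        if key in index:
            counts[index[key]] += 1
    windows["n"] = counts

    out = (
        windows.groupby("bin")
        .agg(gc=("gc", "mean"), m=("n", "size"), n=("n", "sum"))
        .reset_index()
    )
    out["rate"] = out["n"] / (out["m"] * g * window)
    return out


def gene_density_rates(calls, reference: Reference, g: int, bin_size: int = 100_000):
    """Mutation rates in high vs low gene-density bins with a two-tailed t test.

    Each chromosome is tiled into ``bin_size`` bins (last partial bin kept with
    its own length); bins are split at the median per-bin gene bp into high and
    low groups, and per-bin rates n/(g*len) feed a Student's t test.
    """
    genes = reference.features.query("type == 'gene'")
    rows = []
    for chrom, seq in reference.chromosomes.items():
        length = len(seq)
        gmask = np.zeros(length, dtype=bool)
        for r in genes[genes["chrom"] == chrom].itertuples(index=False):
            gmask[r.start : r.end] = True
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            rows.append((chrom, start, end, int(gmask[start:end].sum()), 0))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_bp", "n"])
    for call in calls:
        sel = (
            (bins["chrom"] == call.chrom)
            & (bins["start"] < call.pos)
            & (call.pos <= bins["end"])
        )
        bins.loc[sel, "n"] += 1
    median = bins["gene_bp"].median()
    bins["group"] = np.where(bins["gene_bp"] > median, "high", "low")
    bins["rate"] = bins["n"] / (g * (bins["end"] - bins["start"]))
    high = bins[bins["group"] == "high"]
    low = bins[bins["group"] == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("need at least 2 bins per gene-density group")
    t, p = stats.ttest_ind(high["rate"], low["rate"])

    def group_rate(sub):
        return sub["n"].sum() / (g * (sub["end"] - sub["start"]).sum())

    return {
        "median_gene_bp": float(median),
        "rate_high": float(group_rate(high)),
        "rate_low": float(group_rate(low)),
        "n_bins_high": int(len(high)),
        "n_bins_low": int(len(low)),
        "t": float(t),
        "p": float(p),
    }, bins
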