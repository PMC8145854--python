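"""Cytosine methylation summaries and methylation x TE mutability interaction.

A cytosine's methylation level is reads(mC) / (reads(mC) + reads(C)). Status
calling uses a one-sided binomial test of the methylated read count against
the bisulfite non-conversion error rate, with multiple-testing correction
(Benjamini-Hochberg) at q <= 0.05 — the standard convention for
bisulfite-based methylation callers.

The interaction of methylation and transposable-element membership with
mutation probability is fit as a main-effects logistic regression
logit P(mutated) = b0 + b1*methylated + b2*in_TE over assayed cytosines,
collapsed to covariate patterns and fit as a binomial GLM (identical
likelihood, constant memory).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import Reference
from .rates import mutation_rate

CONTEXTS = ("CG", "CHG", "CHH")


def methylation_levels(sites: pd.DataFrame) -> pd.Series:
    total = sites["count_methylated"] + sites["count_unmethylated"]
    return sites["count_methylated"] / total


def call_methylation_status(
    sites: pd.DataFrame, error_rate: float = 0.02, q: float = 0.05
) -> pd.Series:
    """Binomial test of methylated reads vs the conversion error rate, BH q<=0.05."""
    total = (sites["count_methylated"] + sites["count_unmethylated"]).to_numpy()
    k = sites["count_methylated"].to_numpy()
    pvals = stats.binom.sf(k - 1, total, error_rate)
    ok = total > 0
    called = np.zeros(len(sites), dtype=bool)
    if ok.any():
        rejected, _, _, _ = multipletests(pvals[ok], alpha=q, method="fdr_bh")
        called[ok] = rejected
    return pd.Series(called, index=sites.index)


def methylation_summary(sites: pd.DataFrame, status_column: str = "methylated") -> dict:
    """Per-context methylated-cytosine counts and overall %mC.

    Sites with zero total reads are excluded (their level is undefined);
    the number excluded is reported.
    """
    total_reads = sites["count_methylated"] + sites["count_unmethylated"]
    excluded = int((total_reads == 0).sum())
    ok = sites[total_reads > 0]
    out = {"n_excluded_zero_coverage": excluded, "contexts": {}}
    for ctx in CONTEXTS:
        sub = ok[ok["context"] == ctx]
        n_meth = int(sub[status_column].sum())
        out["contexts"][ctx] = {
            "n_sites": int(len(sub)),
            "n_methylated": n_meth,
            "percent_methylated": 100.0 * n_meth / len(sub) if len(sub) else float("nan"),
        }
    n_all = int(len(ok))
    n_meth_all = int(ok[status_column].sum())
    out["n_sites"] = n_all
    out["n_methylated"] = n_meth_all
    out["percent_methylated"] = 100.0 * n_meth_all / n_all if n_all else float("nan")
    return out


def _mutated_site_keys(calls) -> set:
    """(chrom, 0-based pos) of SNV calls at C:G sites."""
    keys = set()
    for c in calls:
        if c.mtype == "SNV" and c.ref in "CG":
            keys.add((c.chrom, c.pos - 1))
    return keys


def mutated_base_enrichment(
    calls, sites: pd.DataFrame, context: str, status_column: str = "methylated"
):
    """Fisher's exact test: methylation at mutated bases vs genome-wide.

    2x2 table rows are (mutated cytosines, all other assayed cytosines),
    columns (methylated, nonmethylated), within one context. Returns a dict
    with the table, odds ratio, and two-sided p; raises if no mutated
    cytosine of the context was assayed.
    """
    sub = sites[sites["context"] == context]
    mut_keys = _mutated_site_keys(calls)
    site_keys = list(zip(sub["chrom"], sub["pos"]))
    is_mut = np.array([k in mut_keys for k in site_keys], dtype=bool)
    meth = sub[status_column].to_numpy().astype(bool)
    a = int(np.sum(is_mut & meth))
    b = int(np.sum(is_mut & ~meth))
    c = int(np.sum(~is_mut & meth))
    d = int(np.sum(~is_mut & ~meth))
    if a + b == 0:
        raise ValueError(f"no mutated {context} cytosines among assayed sites")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "context": context,
        "table": [[a, b], [c, d]],
        "odds_ratio": float(odds),
        "p": float(p),
        "percent_methylated_mutated": 100.0 * a / (a + b),
        "percent_methylated_genome": 100.0 * c / (c + d) if c + d else float("nan"),
    }


def enrichment_by_context(calls, sites, status_column="methylated", n_tests=3):
    """Per-context enrichment with Bonferroni-corrected p alongside raw p."""
    rows = []
    for ctx in CONTEXTS:
        try:
            r = mutated_base_enrichment(calls, sites, ctx, status_column)
        except ValueError:
            rows.append({"context": ctx, "odds_ratio": None, "p": None, "p_bonferroni": None})
            continue
        r["p_bonferroni"] = min(r["p"] * n_tests, 1.0)
        rows.append(r)
    return pd.DataFrame(rows)


def build_site_table(reference: Reference, calls, status_column="methylated") -> pd.DataFrame:
    """One row per assayed cytosine in the callable mask: mutated/methylated/in_TE."""
    m = reference.methylation
    rows = []
    mut_keys = _mutated_site_keys(calls)
    for chrom, grp in m.groupby("chrom"):
        mask = reference.callable_mask[chrom]
        pos = grp["pos"].to_numpy()
        ok = mask[pos]
        te = np.zeros(len(reference.chromosomes[chrom]), dtype=bool)
        for s, e in reference.te_intervals(chrom):
            te[s:e] = True
        sub = grp[ok]
        mutated = np.array([(chrom, p) in mut_keys for p in sub["pos"]])
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sub["pos"].to_numpy(),
                    "context": sub["context"].to_numpy(),
                    "methylated": sub[status_column].to_numpy().astype(int),
                    "in_te": te[sub["pos"].to_numpy()].astype(int),
                    "mutated": mutated.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def interaction_model(site_table: pd.DataFrame, interaction: bool = False) -> pd.DataFrame:
    """Logistic regression of mutation on methylation and TE membership.

    ``site_table`` needs integer 0/1 columns mutated, methylated, in_te.
    Rows are collapsed to covariate patterns and fit as a binomial GLM.
    Complete separation (a covariate pattern class with no variation that
    makes the MLE diverge) is detected and reported as an error.
    """
    if site_table["mutated"].sum() == 0:
        raise ValueError("no events: every site is unmutated")
    if site_table["mutated"].all():
        raise ValueError("no non-events: every site is mutated")
    grouped = (
        site_table.groupby(["methylated", "in_te"])
        .agg(events=("mutated", "sum"), total=("mutated", "size"))
        .reset_index()
    )
    cols = ["methylated", "in_te"]
    X = grouped[cols].astype(float)
    if interaction:
        X = X.assign(methylated_x_te=X["methylated"] * X["in_te"])
    X = sm.add_constant(X, has_constant="add")
    endog = np.column_stack([grouped["events"], grouped["total"] - grouped["events"]])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 30):
        raise ValueError("complete separation: a coefficient diverged")
    out = pd.DataFrame(
        {
            "term": X.columns,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "odds_ratio": np.exp(res.params.to_numpy()),
            "p": res.pvalues.to_numpy(),
        }
    )
    out.attrs["llf"] = float(res.llf)
    null_model = sm.GLM(endog, np.ones((len(grouped), 1)), family=sm.families.Binomial())
    out.attrs["llf_null"] = float(null_model.fit().llf)
    return out


def strata_rates(site_table: pd.DataFrame, g: int, n_lineages: int) -> pd.DataFrame:
    """Mutation rate in the four TE x methylation strata.

    Rate per stratum = mutated sites / (stratum sites * g * n_lineages);
    empty strata get a None rate (undefined).
    """
    rows = []
    for te in (0, 1):
        for meth in (0, 1):
            sub = site_table[(site_table["in_te"] == te) & (site_table["methylated"] == meth)]
            b = len(sub)
            n = int(sub["mutated"].sum())
            rate = mutation_rate(n, g, b * n_lineages) if b else None
            rows.append(
                {
                    "stratum": f"{'TE' if te else 'nonTE'}x{'methylated' if meth else 'nonmethylated'}",
                    "n_sites": b,
                    "n_mutated": n,
                    "rate": rate,
                }
            )
    return pd.DataFrame(rows)
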