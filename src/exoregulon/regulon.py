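"""Differential expression thresholds, direct-regulon inference and COG tests.

A gene is differentially expressed (DE) when |log2 fold-change| of the
knockout relative to wild type is at least 1 (two-fold) with a
Benjamini-Hochberg adjusted P below 0.05.  The direct regulon of a TF is
the intersection of its bound genes with the DE genes; a direct target
up-regulated upon deleting the TF is repressed by it, a down-regulated one
activated.  Regulators are classified by target-gene count (single-target,
local with <100 targets, global with >100), and target sets are tested for
enrichment of COG functional categories with an upper-tail hypergeometric
test at P < 0.01.

The built-in count-based DE test is a deliberately simple stand-in (CPM
normalization, pooled method-of-moments negative-binomial dispersion, Wald
test on the log2 ratio); studies with real data should supply an external
DE table (e.g. from DESeq2), from which only the threshold rule and BH
adjustment here are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "is_de", "direction"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (FDR q-values).

    q(i) = min_{j >= i} m * p(j) / j over the ascending sort, capped at 1,
    returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def simple_de_test(
    counts: pd.DataFrame, groups: list[str], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Two-condition Wald test on normalized counts (stand-in DE caller).

    `counts` is genes x samples; `groups` labels each column with one of
    exactly two condition names (reference first, e.g. WT then KO), each
    with >= 2 replicates.  Counts are scaled to counts-per-million, the
    negative-binomial dispersion (variance = mu + alpha mu^2) is estimated
    per gene by method of moments and pooled across genes by the median,
    and the per-gene log2 ratio is tested with a normal Wald statistic via
    the delta method.  P-values are BH-adjusted.
    """
    labels = pd.unique(pd.Series(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    groups = np.asarray(groups)
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} needs >= 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("every sample needs nonzero total counts")
    cpm = counts.to_numpy(dtype=float) / lib * 1e6

    ref, alt = labels[0], labels[1]
    a = cpm[:, groups == ref]
    b = cpm[:, groups == alt]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    # pooled method-of-moments NB dispersion on the normalized scale;
    # the ratio-of-sums estimator is nearly unbiased at few replicates
    var_w = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
    mean_w = (mean_a + mean_b) / 2
    denom = float(np.sum(mean_w**2))
    alpha_hat = max(0.0, float(np.sum(var_w - mean_w)) / denom) if denom > 0 else 0.0

    # Wald statistic with the NB variance evaluated at the null (pooled) mean
    def var_log2_mean(mu: np.ndarray, n: int) -> np.ndarray:
        v = (mu + alpha_hat * mu**2) / n  # variance of the replicate mean
        return v / ((mu + pseudocount) ** 2 * np.log(2) ** 2)

    se = np.sqrt(var_log2_mean(mean_w, a.shape[1]) + var_log2_mean(mean_w, b.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        }
    )


def call_de(records: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Flag DE genes: |log2fc| >= lfc_min (inclusive) and padj < alpha (strict)."""
    df = records.copy()
    up = (df["log2fc"] >= lfc_min) & (df["padj"] < alpha)
    down = (df["log2fc"] <= -lfc_min) & (df["padj"] < alpha)
    df["is_de"] = up | down
    df["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return df


def direct_regulon(bound_genes, de: pd.DataFrame) -> dict:
    """Intersect bound genes with DE genes and infer regulatory mode.

    Direction is knockout-vs-wild-type: a direct target up in the knockout
    is repressed by the TF, one down is activated.  Returns the direct
    target table plus the rounded percentages the per-TF summaries report.
    """
    bound = sorted(set(bound_genes))
    de_ix = de.set_index("gene_id")
    direct_rows = []
    for g in bound:
        if g in de_ix.index and bool(de_ix.loc[g, "is_de"]):
            mode = "repressed" if de_ix.loc[g, "direction"] == "up" else "activated"
            direct_rows.append({"gene_id": g, "direction": de_ix.loc[g, "direction"], "mode": mode})
    direct = pd.DataFrame(direct_rows, columns=["gene_id", "direction", "mode"])
    n_bound, n_direct = len(bound), len(direct)
    n_rep = int((direct["mode"] == "repressed").sum()) if n_direct else 0
    n_act = n_direct - n_rep
    return {
        "direct_targets": direct,
        "n_bound": n_bound,
        "n_direct": n_direct,
        "n_repressed": n_rep,
        "n_activated": n_act,
        "pct_direct": round(100 * n_direct / n_bound) if n_bound else 0,
        "pct_repressed": round(100 * n_rep / n_direct) if n_direct else None,
    }


def classify_regulator(
    n_target_genes: int,
    global_min: int = 101,
    nucleoid_min: int | None = None,
) -> str:
    """Target-count regulator classes: single-target, local (<100), global (>100).

    Nucleoid-associated proteins (hundreds of targets) are only labelled
    when an explicit higher `nucleoid_min` threshold is configured.
    """
    n = int(n_target_genes)
    if n < 0:
        raise ValueError("target-gene count must be >= 0")
    if n == 0:
        return "unclassified"
    if n == 1:
        return "single_target"
    if nucleoid_min is not None and n >= nucleoid_min:
        return "nucleoid_associated"
    if n >= global_min:
        return "global"
    return "local"


@dataclass
class COGEnrichment:
    category: str
    k: int  # targets in category
    n: int  # targets with a COG label
    K: int  # universe genes in category
    N: int  # universe size
    pvalue: float
    significant: bool


def cog_enrichment(
    target_genes, universe: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of COG categories in a target set.

    P = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n), evaluated in
    log-space via the hypergeometric survival function.  Targets without a
    COG label are excluded from n (their count is reported in the
    `n_unlabelled` attribute of the returned frame).
    """
    uni = universe.copy()
    uni["cog"] = uni["cog"].fillna("")
    ids = set(uni["gene_id"])
    targets = sorted(set(target_genes))
    missing = [g for g in targets if g not in ids]
    if missing:
        raise ValueError(f"target genes not in universe: {missing[:5]}")
    uni_lab = uni[uni["cog"] != ""]
    tgt = uni_lab[uni_lab["gene_id"].isin(targets)]
    n_unlabelled = len(targets) - len(tgt)
    N, n = len(uni_lab), len(tgt)
    rows = []
    for cat, grp in uni_lab.groupby("cog"):
        K = len(grp)
        k = int((tgt["cog"] == cat).sum())
        assert k <= min(n, K)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append(
            {
                "category": cat,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "pvalue": min(p, 1.0),
                "significant": p < alpha,
            }
        )
    out = pd.DataFrame(rows, columns=["category", "k", "n", "K", "N", "pvalue", "significant"])
    out.attrs["n_unlabelled"] = n_unlabelled
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)


def regulon_summary(
    tf: str,
    assignments,
    cooccupancy_calls,
    direct: dict,
    count_basis: str = "genes",
) -> dict:
    """Per-TF tallies: sites, location split, co-occupancy, direct regulon, class.

    The regulator class is computed from the distinct-target-gene count by
    default; `count_basis="sites"` classifies on raw binding-site count
    instead, and both tallies are always reported.
    """
    from .annotate import summarize_locations
    from .cooccupancy import summarize_cooccupancy

    loc = summarize_locations(assignments)
    co = summarize_cooccupancy(cooccupancy_calls)
    n_sites = loc["total"]
    n_genes = direct["n_bound"]
    basis = n_sites if count_basis == "sites" else n_genes
    return {
        "tf": tf,
        "n_sites": n_sites,
        "n_regulatory": loc["n_regulatory"],
        "n_intragenic": loc["n_intragenic"],
        "n_cooccupied": co["overlap_total"],
        "n_bound_genes": n_genes,
        "n_direct": direct["n_direct"],
        "n_repressed": direct["n_repressed"],
        "n_activated": direct["n_activated"],
        "pct_direct": direct["pct_direct"],
        "regulator_class": classify_regulator(basis),
    }
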