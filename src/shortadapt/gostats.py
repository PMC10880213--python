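"""GO-term over-representation and selection-strength testing.

Over-representation is an upper-tail hypergeometric test of the overlap
between a selected gene set and each term's genes, BH-adjusted across
terms.  Selection strength asks a different question: whether the genes of
a term collectively show elevated differentiation (mean FST) and reduced
captive/wild diversity ratio, against a null of equal-size random gene
sets drawn from the universe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (step-up)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    selected_genes, universe, go_map: dict[str, set[str]]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in a gene list.

    ``p_hyper = P(X >= k)`` for overlap ``k`` between the ``n`` selected
    genes and the ``K`` universe genes of the term, out of ``N`` universe
    genes.  BH-adjusted q-values across terms are included.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    selected = set(selected_genes)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, genes in sorted(go_map.items()):
        term_genes = genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term_id", "k_overlap", "K_term", "n_selected", "N_universe", "p_hyper"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p_hyper"].to_numpy())
    return df


def gene_window_stats(
    windows: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene mean FST and mean pi-ratio over overlapping scan windows.

    A gene's statistic is the unweighted mean of every window overlapping
    its body; genes overlapping no usable window are dropped.
    """
    rows = []
    for gene in genes.reset_index().itertuples(index=False):
        sub = windows[
            (windows["chrom"] == gene.chrom)
            & (windows["end"] > gene.start)
            & (windows["start"] < gene.end)
        ].dropna(subset=["fst", "pi_ratio"])
        if len(sub):
            rows.append((gene.gene_id, float(sub["fst"].mean()), float(sub["pi_ratio"].mean())))
    return pd.DataFrame(rows, columns=["gene_id", "mean_fst", "mean_pi_ratio"]).set_index(
        "gene_id"
    )


def term_selection_strength(
    gene_stats: pd.DataFrame,
    go_map: dict[str, set[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.01,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Permutation test of per-term mean FST and mean pi-ratio.

    For each term with >= 3 genes carrying statistics, the observed means
    are compared with ``n_perm`` equal-size random gene sets from the
    universe.  One-sided by default, encoding selection in captivity:
    ``p_fst`` is the fraction of null means >= observed (elevated
    differentiation) and ``p_pi`` the fraction <= observed (reduced
    captive/wild ratio), both with the +1 correction.  A term is
    ``significant`` when both p-values are <= ``alpha``.
    """
    rng = np.random.default_rng(seed)
    fst_all = gene_stats["mean_fst"].to_numpy()
    pi_all = gene_stats["mean_pi_ratio"].to_numpy()
    index = {g: i for i, g in enumerate(gene_stats.index)}
    N = len(gene_stats)

    null_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def null_means(m: int) -> tuple[np.ndarray, np.ndarray]:
        if m not in null_cache:
            fst_means = np.empty(n_perm)
            pi_means = np.empty(n_perm)
            for i in range(n_perm):
                pick = rng.choice(N, size=m, replace=False)
                fst_means[i] = fst_all[pick].mean()
                pi_means[i] = pi_all[pick].mean()
            null_cache[m] = (fst_means, pi_means)
        return null_cache[m]

    rows = []
    for term, genes in sorted(go_map.items()):
        idx = [index[g] for g in genes if g in index]
        if len(idx) < 3:
            warnings.warn(f"term {term} has fewer than 3 genes with statistics; skipped")
            continue
        obs_fst = float(fst_all[idx].mean())
        obs_pi = float(pi_all[idx].mean())
        nf, npi = null_means(len(idx))
        p_fst = (int((nf >= obs_fst).sum()) + 1) / (n_perm + 1)
        p_pi = (int((npi <= obs_pi).sum()) + 1) / (n_perm + 1)
        if two_sided:
            p_fst = min(1.0, 2 * min(p_fst, (int((nf <= obs_fst).sum()) + 1) / (n_perm + 1)))
            p_pi = min(1.0, 2 * min(p_pi, (int((npi >= obs_pi).sum()) + 1) / (n_perm + 1)))
        rows.append((term, len(idx), obs_fst, obs_pi, p_fst, p_pi, p_fst <= alpha and p_pi <= alpha))
    return pd.DataFrame(
        rows,
        columns=["term_id", "n_genes", "mean_fst", "mean_pi_ratio", "p_fst", "p_pi", "significant"],
    )
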