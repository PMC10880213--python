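"""Sliding-window diversity/differentiation scan and selected-region calls.

The scan tiles each chromosome with 40-kb windows advancing in 20-kb steps
and computes, per window, nucleotide diversity per population (theta-pi),
their captive/wild ratio, and the weighted Weir-Cockerham FST.  Candidate
sweep regions are the joint empirical tails of the ratio and FST
distributions; a region is flagged robust when it contains at least one
SNP whose captive-wild allele-frequency difference is >= 0.6.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypePanel

WINDOW_BP = 40_000
STEP_BP = 20_000


def iter_windows(chrom_len: int, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP):
    """Half-open windows starting at multiples of the step; the last one
    truncates at the chromosome end."""
    for start in range(0, chrom_len, step_bp):
        yield start, min(start + window_bp, chrom_len)


def _group_allele_counts(panel: GenotypePanel, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(called allele count n, alt allele count c) per site for one group."""
    g = panel.genotypes[rows]
    called = g != MISSING
    n = 2 * called.sum(axis=0)
    c = np.where(called, g, 0).sum(axis=0)
    return n.astype(float), c.astype(float)


def _chrom_lengths(panel: GenotypePanel, chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    if chrom_lengths is not None:
        return chrom_lengths
    # fall back to the last SNP rounded up to a step boundary
    return {
        c: int(np.ceil(v / STEP_BP)) * STEP_BP for c, v in panel.chrom_span().items()
    }


def window_diversity(
    panel: GenotypePanel,
    group_by: str = "population",
    window_bp: int = WINDOW_BP,
    step_bp: int = STEP_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed theta-pi per group (per-bp, divided by the full window span).

    Site diversity is ``2 c (n - c) / (n (n - 1))`` with ``n`` the called
    allele count and ``c`` the alt count within the group; sites with
    ``n < 2`` in a group are skipped for that group.
    """
    groups = panel.group_indices(group_by)
    lengths = _chrom_lengths(panel, chrom_lengths)
    site_pi = {}
    for gname, rows in groups.items():
        n, c = _group_allele_counts(panel, rows)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = 2.0 * c * (n - c) / (n * (n - 1.0))
        pi[n < 2] = 0.0
        site_pi[gname] = pi

    sites = panel.sites.reset_index(drop=True)
    rows_out = []
    for chrom, length in lengths.items():
        sub = sites[sites["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy() - 1  # windows are 0-based half-open
        cols = sub.index.to_numpy()
        for start, end in iter_windows(length, window_bp, step_bp):
            inside = cols[(pos0 >= start) & (pos0 < end)]
            row = {"chrom": chrom, "start": start, "end": end, "n_snps": len(inside)}
            for gname in groups:
                row[f"pi_{gname}"] = float(site_pi[gname][inside].sum()) / (end - start)
            rows_out.append(row)
    return pd.DataFrame(rows_out)


def wc_site_components(panel: GenotypePanel) -> pd.DataFrame:
    """Per-site Weir-Cockerham (1984) variance components for two populations.

    Returns columns ``a`` (among-population), ``b`` (among individuals
    within populations) and ``c`` (within individuals); the weighted window
    estimator is ``sum(a) / sum(a + b + c)``.  Sites with fewer than two
    called genotypes in either population get NaN components.
    """
    groups = panel.group_indices("population")
    if len(groups) != 2:
        raise ValueError("Weir-Cockerham components need exactly 2 populations")
    (_, rows1), (_, rows2) = sorted(groups.items())
    stats_pp = []
    for rows in (rows1, rows2):
        g = panel.genotypes[rows]
        called = g != MISSING
        n_ind = called.sum(axis=0).astype(float)  # diploid individuals called
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called, g, 0).sum(axis=0) / (2.0 * n_ind)
            h = np.where(called & (g == 1), 1, 0).sum(axis=0) / n_ind
        stats_pp.append((n_ind, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats_pp
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    out = panel.sites[["chrom", "pos"]].copy()
    out["a"], out["b"], out["c"] = a, b, c
    return out


def window_fst(
    panel: GenotypePanel,
    window_bp: int = WINDOW_BP,
    step_bp: int = STEP_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Weighted Weir-Cockerham FST per window (negative values retained)."""
    comp = wc_site_components(panel)
    lengths = _chrom_lengths(panel, chrom_lengths)
    rows_out = []
    for chrom, length in lengths.items():
        sub = comp[comp["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy() - 1
        a = sub["a"].to_numpy()
        tot = a + sub["b"].to_numpy() + sub["c"].to_numpy()
        for start, end in iter_windows(length, window_bp, step_bp):
            inside = (pos0 >= start) & (pos0 < end) & ~np.isnan(tot)
            denom = tot[inside].sum()
            fst = a[inside].sum() / denom if denom > 0 else np.nan
            rows_out.append(
                {"chrom": chrom, "start": start, "end": end, "n_snps": int(inside.sum()), "fst": fst}
            )
    return pd.DataFrame(rows_out)


def window_stats(
    panel: GenotypePanel,
    chrom_lengths: dict[str, int] | None = None,
    window_bp: int = WINDOW_BP,
    step_bp: int = STEP_BP,
) -> pd.DataFrame:
    """Combined per-window table: pi per population, pi ratio and FST.

    ``pi_ratio`` is captive/wild and is missing (NaN) where the wild window
    diversity is zero.
    """
    div = window_diversity(panel, "population", window_bp, step_bp, chrom_lengths)
    fst = window_fst(panel, window_bp, step_bp, chrom_lengths)
    out = div.merge(fst.drop(columns=["n_snps"]), on=["chrom", "start", "end"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["pi_captive"] / out["pi_wild"]
    out["pi_ratio"] = np.where(out["pi_wild"] > 0, ratio, np.nan)
    return out


def snp_frequency_table(panel: GenotypePanel) -> pd.DataFrame:
    """Alt-allele frequency per population and the absolute difference.

    Sites uncalled in either population are dropped with a warning.
    """
    groups = panel.group_indices("population")
    if set(groups) != {"captive", "wild"}:
        raise ValueError("expected populations 'captive' and 'wild'")
    n_c, c_c = _group_allele_counts(panel, groups["captive"])
    n_w, c_w = _group_allele_counts(panel, groups["wild"])
    ok = (n_c > 0) & (n_w > 0)
    if (~ok).any():
        warnings.warn(f"dropped {int((~ok).sum())} sites uncalled in one population")
    out = panel.sites.loc[ok, ["chrom", "pos"]].reset_index(drop=True)
    out["freq_captive"] = c_c[ok] / n_c[ok]
    out["freq_wild"] = c_w[ok] / n_w[ok]
    out["abs_diff"] = np.abs(out["freq_captive"] - out["freq_wild"])
    return out


def identify_selected_regions(
    windows: pd.DataFrame,
    snps: pd.DataFrame,
    tail: float = 0.05,
    diff_cut: float = 0.6,
) -> pd.DataFrame:
    """Joint-tail selected regions with a SNP-frequency robustness flag.

    Thresholds are empirical quantiles over windows with non-missing
    ``pi_ratio`` and ``fst``.  Captive-direction regions sit in the left
    ``tail`` of the ratio distribution (diversity lost in captivity) with
    FST in the right tail; wild-direction regions take the right ratio
    tail.  Comparisons are inclusive.  ``robust`` marks windows containing
    at least one SNP with ``abs_diff >= diff_cut``.
    """
    ok = windows.dropna(subset=["pi_ratio", "fst"])
    if len(ok) < 20:
        raise ValueError(f"only {len(ok)} usable windows; need at least 20")
    q_lo = float(np.quantile(ok["pi_ratio"], tail))
    q_hi = float(np.quantile(ok["pi_ratio"], 1 - tail))
    fst_hi = float(np.quantile(ok["fst"], 1 - tail))
    captive = (ok["pi_ratio"] <= q_lo) & (ok["fst"] >= fst_hi)
    wild = (ok["pi_ratio"] >= q_hi) & (ok["fst"] >= fst_hi)
    sel = ok[captive | wild].copy()
    sel["direction"] = np.where(captive[captive | wild], "captive", "wild")

    strong = snps[snps["abs_diff"] >= diff_cut]
    robust = []
    for row in sel.itertuples(index=False):
        hits = strong[
            (strong["chrom"] == row.chrom)
            & (strong["pos"] - 1 >= row.start)
            & (strong["pos"] - 1 < row.end)
        ]
        robust.append(len(hits) > 0)
    sel["robust"] = robust
    return sel.reset_index(drop=True)


def association_scan(
    panel: GenotypePanel, case: str = "captive", control: str = "wild"
) -> pd.DataFrame:
    """Per-SNP allele-count association test between two populations.

    A 1-df chi-square without continuity correction on the 2x2 allele table
    (case alt/ref vs control alt/ref); Fisher's exact test is substituted
    whenever any expected cell is below 5.  Monomorphic sites get p = 1.
    """
    groups = panel.group_indices("population")
    for g in (case, control):
        if g not in groups or len(groups[g]) == 0:
            raise ValueError(f"population {g!r} empty or unknown")
    n1, c1 = _group_allele_counts(panel, groups[case])
    n2, c2 = _group_allele_counts(panel, groups[control])
    rows = []
    for i in range(panel.n_sites):
        table = np.array([[c1[i], n1[i] - c1[i]], [c2[i], n2[i] - c2[i]]])
        total = table.sum()
        alt_tot, ref_tot = table[:, 0].sum(), table[:, 1].sum()
        if total == 0 or alt_tot == 0 or ref_tot == 0:
            rows.append((0.0, 1.0, "chi2"))
            continue
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        if (expected < 5).any():
            _, p = stats.fisher_exact(table.astype(int))
            rows.append((np.nan, float(p), "fisher"))
        else:
            chi2 = float(((table - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(chi2, df=1))
            rows.append((chi2, max(p, np.finfo(float).tiny), "chi2"))
    out = panel.sites[["chrom", "pos"]].copy()
    out[["chi2", "p", "test"]] = pd.DataFrame(rows, index=out.index)
    return out


# ---------------------------------------------------------------------------
# composition of selected regions vs the genome
# ---------------------------------------------------------------------------

def coverage_fraction(region: tuple[str, int, int], intervals: list[tuple]) -> float:
    """Fraction of a half-open region covered by a set of half-open intervals."""
    chrom, start, end = region
    covered = np.zeros(end - start, dtype=bool)
    for ic, istart, iend in intervals:
        if ic != chrom:
            continue
        lo, hi = max(istart, start), min(iend, end)
        if lo < hi:
            covered[lo - start : hi - start] = True
    return float(covered.mean())


def region_composition_compare(
    regions: list[tuple],
    chrom_lengths: dict[str, int],
    feature_intervals: dict[str, list[tuple]] | None = None,
    gc_windows: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of region composition against the genome.

    For each repeat class (and optionally GC content), the statistic is the
    mean coverage fraction (mean GC) over the query regions; the null is
    built from length- and chromosome-matched random placements.  Two-sided
    permutation p-values with the +1 correction.
    """
    rng = np.random.default_rng(seed)
    for chrom, start, end in regions:
        if end - start > chrom_lengths[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} longer than chromosome")

    def random_placement():
        out = []
        for chrom, start, end in regions:
            span = end - start
            s = int(rng.integers(0, chrom_lengths[chrom] - span + 1))
            out.append((chrom, s, s + span))
        return out

    rows = []
    feature_intervals = feature_intervals or {}
    for cls, intervals in feature_intervals.items():
        obs = float(np.mean([coverage_fraction(r, intervals) for r in regions]))
        null = np.array(
            [
                np.mean([coverage_fraction(r, intervals) for r in random_placement()])
                for _ in range(n_perm)
            ]
        )
        ge = int((null >= obs - 1e-15).sum())
        le = int((null <= obs + 1e-15).sum())
        p = min(1.0, 2.0 * min(ge + 1, le + 1) / (n_perm + 1))
        rows.append((cls, obs, float(null.mean()), p))

    if gc_windows is not None:
        def mean_gc(regs):
            vals = []
            for chrom, start, end in regs:
                sub = gc_windows[
                    (gc_windows["chrom"] == chrom)
                    & (gc_windows["end"] > start)
                    & (gc_windows["start"] < end)
                ]
                if len(sub):
                    vals.append(sub["gc"].mean())
            return float(np.mean(vals)) if vals else np.nan

        obs = mean_gc(regions)
        null = np.array([mean_gc(random_placement()) for _ in range(n_perm)])
        ge = int((null >= obs - 1e-15).sum())
        le = int((null <= obs + 1e-15).sum())
        p = min(1.0, 2.0 * min(ge + 1, le + 1) / (n_perm + 1))
        rows.append(("GC", obs, float(np.nanmean(null)), p))
    return pd.DataFrame(rows, columns=["feature", "observed", "null_mean", "p"])
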