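"""Population-effect elimination: PCA, exhaustive matched-subset search,
identity-by-state relatedness and LD decay.

The matching problem: given captive individuals and a larger wild pool,
pick the ``k`` wild individuals closest to the captive cohort in the top
principal-component space, so the downstream captive/wild contrast measures
the environment rather than population structure.  Every k-subset of the
wild pool can be enumerated and scored (28 choose 11 = 21,474,180 for the
motivating design).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypePanel


@dataclasses.dataclass
class PCAProjection:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    explained_fraction: np.ndarray  # k values, non-increasing

    def coords_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return self.coordinates[[lookup[s] for s in ids]]


@dataclasses.dataclass
class SubsetMatch:
    chosen_wild: tuple[str, ...]
    score: float
    n_subsets_evaluated: int


@dataclasses.dataclass
class DSTMatrix:
    sample_ids: list[str]
    dst: np.ndarray  # symmetric, in [0, 1], NaN where no co-called sites

    def submatrix(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in ids])
        return self.dst[np.ix_(idx, idx)]


def compute_pca(panel: GenotypePanel, k: int = 3) -> PCAProjection:
    """Sample PCA on frequency-standardised dosages.

    Dosages are mean-centred per site and divided by ``sqrt(2 p (1-p))``
    with ``p`` the sample alt-allele frequency (the Patterson convention;
    unscaled PCA is dominated by common sites).  Missing genotypes are
    imputed to the site mean.  Coordinates are the projections onto the top
    ``k`` axes; ``explained_fraction`` is eigenvalue / trace.
    """
    if panel.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = panel.genotypes.astype(float)
    X[panel.genotypes == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    seg = (p > 0) & (p < 1)
    if seg.sum() < k:
        raise ValueError(f"need at least {k} segregating sites, found {seg.sum()}")
    X = X[:, seg]
    p = p[seg]
    X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    total = float(np.sum(X * X))
    if total <= 1e-12:
        raise ValueError("zero total variance: all samples genotypically identical")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * S[:k]
    explained = (S[:k] ** 2) / np.sum(S**2)
    return PCAProjection(
        sample_ids=list(panel.sample_ids),
        coordinates=coords,
        explained_fraction=explained,
    )


def _iter_index_chunks(n: int, k: int, chunk: int):
    """Yield (chunk_size, k) index arrays over all k-combinations of range(n)."""
    it = itertools.combinations(range(n), k)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            return
        yield np.array(block, dtype=np.int32)


def match_wild_subset(
    proj: PCAProjection,
    captive_ids,
    wild_ids,
    k: int,
    score: str = "centroid",
    chunk: int = 200_000,
) -> SubsetMatch:
    """Pick the k wild samples closest to the captive cohort in PC space.

    ``score='centroid'`` enumerates every k-subset of the wild pool and
    scores it by the Euclidean distance between the subset centroid and the
    captive centroid; ties are broken by the mean captive-to-member
    distance, then by lexicographic ids.  ``score='per-individual'`` ranks
    each wild sample by its mean distance to the captive samples and keeps
    the k closest (one pass, no enumeration).
    """
    wild_ids = sorted(wild_ids)
    captive_ids = list(captive_ids)
    n = len(wild_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds wild pool of {n}")
    W = proj.coords_of(wild_ids)
    C = proj.coords_of(captive_ids)
    centroid = C.mean(axis=0)
    cross = np.linalg.norm(W[:, None, :] - C[None, :, :], axis=2).mean(axis=1)

    if score == "per-individual":
        order = np.lexsort((np.array(wild_ids, dtype=object), cross))
        chosen = tuple(sorted(np.array(wild_ids, dtype=object)[order[:k]]))
        sub = proj.coords_of(chosen)
        return SubsetMatch(
            chosen_wild=chosen,
            score=float(np.linalg.norm(sub.mean(axis=0) - centroid)),
            n_subsets_evaluated=n,
        )
    if score != "centroid":
        raise ValueError("score must be 'centroid' or 'per-individual'")

    best_score = np.inf
    best_tie = np.inf
    best: tuple[str, ...] | None = None
    n_eval = 0
    for idx in _iter_index_chunks(n, k, chunk):
        n_eval += len(idx)
        centroids = W[idx].mean(axis=1)
        d = np.linalg.norm(centroids - centroid, axis=1)
        ties = cross[idx].mean(axis=1)
        cut = min(best_score, float(d.min())) + 1e-12
        for j in np.where(d <= cut)[0]:
            cand = tuple(wild_ids[i] for i in idx[j])
            if (
                best is None
                or d[j] < best_score - 1e-12
                or (abs(d[j] - best_score) <= 1e-12 and (ties[j], cand) < (best_tie, best))
            ):
                best_score, best_tie, best = d[j], ties[j], cand
    assert n_eval == math.comb(n, k)
    return SubsetMatch(chosen_wild=best, score=float(best_score), n_subsets_evaluated=n_eval)


def compute_dst_matrix(panel: GenotypePanel) -> DSTMatrix:
    """Pairwise identity-by-state similarity.

    For each sample pair, over sites where both are called,
    ``DST = (#IBS2 + 0.5 #IBS1) / #sites``; with dosages this is
    ``mean(2 - |a - b|) / 2``.  Pairs with no co-called site get NaN with a
    warning.  The diagonal is 1 by definition.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    G = panel.genotypes.astype(float)
    G[panel.genotypes == MISSING] = np.nan
    n = panel.n_samples
    dst = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(G[i] - G[j])
            ok = ~np.isnan(diff)
            if not ok.any():
                warnings.warn(
                    f"no co-called sites for pair {panel.sample_ids[i]},{panel.sample_ids[j]}"
                )
                dst[i, j] = dst[j, i] = np.nan
                continue
            dst[i, j] = dst[j, i] = float(np.mean(2.0 - diff[ok]) / 2.0)
    return DSTMatrix(sample_ids=list(panel.sample_ids), dst=dst)


def _within_between(sub: np.ndarray, n1: int) -> float:
    """Mean within-group DST minus mean between-group DST for a 2-group block."""
    w1 = sub[:n1, :n1][np.triu_indices(n1, 1)]
    w2 = sub[n1:, n1:][np.triu_indices(sub.shape[0] - n1, 1)]
    within = np.concatenate([w1, w2])
    between = sub[:n1, n1:].ravel()
    return float(np.nanmean(within) - np.nanmean(between))


def compare_group_dst(
    dst: DSTMatrix,
    groups: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Two-sided permutation test of within- vs between-group relatedness.

    For every unordered group pair, the statistic is (mean within-group DST)
    minus (mean between-group DST); group labels are permuted ``n_perm``
    times within the pair's pooled samples.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        ids = list(groups[g1]) + list(groups[g2])
        n1 = len(groups[g1])
        sub = dst.submatrix(ids)
        obs = _within_between(sub, n1)
        m = len(ids)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(m)
            stat = _within_between(sub[np.ix_(perm, perm)], n1)
            if abs(stat) >= abs(obs) - 1e-15:
                count += 1
        out[(g1, g2)] = (count + 1) / (n_perm + 1)
    return out


def ld_decay_curve(
    panel: GenotypePanel,
    population: str,
    max_dist_bp: int = 500_000,
    bin_bp: int = 1_000,
) -> pd.DataFrame:
    """Mean genotypic r^2 per distance bin for one population.

    r^2 is the squared Pearson correlation of dosage vectors over
    pairwise-complete samples (the standard unphased surrogate for
    haplotype LD).  Monomorphic pairs are skipped.  Returns a DataFrame
    with ``distance_bin_bp`` (bin start) and ``mean_r2``.
    """
    idx = [i for i, s in enumerate(panel.sample_ids) if panel.population[s] == population]
    if len(idx) < 4:
        raise ValueError(f"population {population!r} has fewer than 4 samples")
    G = panel.genotypes[idx].astype(float)
    G[G == MISSING] = np.nan
    n_bins_out = max_dist_bp // bin_bp + 1
    sums = np.zeros(n_bins_out)
    counts = np.zeros(n_bins_out, dtype=int)
    for chrom, sub in panel.sites.reset_index(drop=True).groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cols = sub.index.to_numpy()
        Gc = G[:, cols]
        for a in range(len(pos)):
            j1 = int(np.searchsorted(pos, pos[a] + max_dist_bp, side="right"))
            if j1 <= a + 1:
                continue
            x = Gc[:, a][:, None]
            Y = Gc[:, a + 1 : j1]
            valid = ~np.isnan(x) & ~np.isnan(Y)
            n_ok = valid.sum(axis=0)
            Xv = np.where(valid, x, 0.0)
            Yv = np.where(valid, Y, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = (Xv * Yv).sum(axis=0) - Xv.sum(axis=0) * Yv.sum(axis=0) / n_ok
                varx = (Xv**2).sum(axis=0) - Xv.sum(axis=0) ** 2 / n_ok
                vary = (Yv**2).sum(axis=0) - Yv.sum(axis=0) ** 2 / n_ok
                r2 = cov**2 / (varx * vary)
            ok = (n_ok >= 4) & (varx > 0) & (vary > 0)
            d_idx = (pos[a + 1 : j1] - pos[a]) // bin_bp
            np.add.at(sums, d_idx[ok], r2[ok])
            np.add.at(counts, d_idx[ok], 1)
    rows = [
        (int(d * bin_bp), sums[d] / counts[d], int(counts[d]))
        for d in np.where(counts > 0)[0]
    ]
    df = pd.DataFrame(rows, columns=["distance_bin_bp", "mean_r2", "n_pairs"])
    df.attrs["population"] = population
    return df
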