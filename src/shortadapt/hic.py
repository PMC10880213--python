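"""Hierarchical chromatin-structure calling from binned contact maps.

The hierarchy, coarse to fine: matrix-resolution evaluation and
Knight-Ruiz balancing; A/B compartments at 100 kb from the leading
eigenvector of the observed/expected correlation matrix, sign-oriented by
gene density; a signed AB-index at 25 kb measuring each fine bin's
preferential contact with A versus B territory; TADs at 25 kb from a
directionality index segmented by a 3-state Gaussian HMM; per-TAD
intactness (log2 observed/expected intra-TAD mass); TAD cliques from
Poisson-significant long-range TAD pairs (Bron-Kerbosch maximal cliques);
and promoter-enhancer interactions at 10 kb within TADs.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genio import ContactMap
from .gostats import bh_adjust


# ---------------------------------------------------------------------------
# resolution evaluation
# ---------------------------------------------------------------------------

def evaluate_matrix_resolution(
    cmap: ContactMap,
    window_sizes_bp=(1_000, 2_000, 5_000, 10_000, 25_000, 40_000, 100_000, 500_000, 1_000_000),
    min_contacts: float = 1000,
    min_fraction: float = 0.80,
) -> int:
    """Smallest window size at which >80% of bins carry >1000 cis contacts.

    Bin totals of the base map are aggregated into each candidate window
    size (sizes below the base resolution are skipped); the chosen
    resolution is the minimum window whose fraction of passing bins
    exceeds ``min_fraction``.
    """
    base = cmap.resolution_bp
    row_tot = cmap.counts.sum(axis=1)
    fractions = {}
    for w in sorted(window_sizes_bp):
        if w < base or w % base:
            continue
        step = w // base
        groups = [row_tot[i : i + step].sum() for i in range(0, len(row_tot), step)]
        frac = float(np.mean([g > min_contacts for g in groups]))
        fractions[w] = frac
        if frac > min_fraction:
            return w
    raise ValueError(f"no window passes {min_fraction:.0%}; fractions: {fractions}")


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

class _KRNonConvergence(Exception):
    pass


def _kr_vector(A: np.ndarray, tol: float, max_outer: int = 100) -> np.ndarray:
    """Knight-Ruiz scaling vector x with diag(x) A diag(x) doubly stochastic.

    Inner-outer Newton iteration with conjugate-gradient inner solves,
    following the published algorithm.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise _KRNonConvergence
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0 or not np.isfinite(denom):
                raise _KRNonConvergence
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = float(((delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = float(((Delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > 2 * n:
                raise _KRNonConvergence
        x = x * y
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            raise _KRNonConvergence
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def _sinkhorn_vector(A: np.ndarray, tol: float, max_iter: int = 20_000) -> np.ndarray:
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        r = x * (A @ x)
        cv = r.std() / r.mean()
        if cv < tol:
            break
        x = x / np.sqrt(r)
    return x


def kr_balance(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 100) -> ContactMap:
    """Knight-Ruiz balance a map so unmasked row sums are equal (CV < tol).

    All-zero rows are masked and left untouched.  On KR non-convergence the
    routine falls back to iterative proportional (Sinkhorn) scaling with a
    warning.  The bias is rescaled so the balanced matrix preserves the
    original total count, keeping balanced values on a count-like scale for
    the downstream Poisson tests.
    """
    keep = cmap.counts.sum(axis=1) > 0
    keep[list(cmap.masked_bins)] = False
    A = cmap.counts[np.ix_(keep, keep)]
    if A.shape[0] == 0:
        raise ValueError("matrix fully masked")
    try:
        x = _kr_vector(A, tol, max_outer=max_iter)
    except _KRNonConvergence:
        warnings.warn("KR did not converge; falling back to iterative proportional scaling")
        x = _sinkhorn_vector(A, tol)
    B = A * np.outer(x, x)
    scale = np.sqrt(cmap.counts.sum() / B.sum())
    x = x * scale
    bias = np.zeros(cmap.n_bins)
    bias[keep] = x
    balanced = cmap.counts * np.outer(bias, bias)
    return ContactMap(
        chrom=cmap.chrom,
        resolution_bp=cmap.resolution_bp,
        counts=balanced,
        balanced=True,
        bias_vector=bias,
        masked_bins=set(np.where(~keep)[0].tolist()),
    )


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DecayCurve:
    """Expected contact count as a function of bin distance (d >= 1)."""

    expected: np.ndarray  # index d, NaN outside the fitted domain (incl. d=0)

    def __call__(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=int)
        return self.expected[np.clip(d, 0, len(self.expected) - 1)]

    @property
    def domain(self) -> np.ndarray:
        return np.where(np.isfinite(self.expected))[0]


def fit_decay_curve(cmap: ContactMap, smooth_window: int = 5) -> DecayCurve:
    """Mean balanced count per diagonal, log-smoothed and made non-increasing.

    The diagonal itself (d = 0) is excluded.  Distances whose mean is zero
    or that involve only masked bins fall outside the fitted domain.
    """
    n = cmap.n_bins
    if n < 10:
        raise ValueError("chromosome too short to fit a decay curve (< 10 bins)")
    keep = cmap.unmasked()
    E = np.full(n, np.nan)
    for d in range(1, n):
        vals = np.diagonal(cmap.counts, offset=d)
        ok = keep[:-d] & keep[d:]
        if ok.any():
            m = float(vals[ok].mean())
            if m > 0:
                E[d] = m
    # moving-average smoothing in log space, then enforce monotone decay
    logE = np.log(E)
    sm = np.full(n, np.nan)
    half = smooth_window // 2
    for d in range(1, n):
        lo, hi = max(1, d - half), min(n, d + half + 1)
        window = logE[lo:hi]
        if np.isfinite(window).any():
            sm[d] = np.nanmean(window)
    out = np.exp(sm)
    finite = np.where(np.isfinite(out))[0]
    if len(finite):
        running = out[finite[0]]
        for d in finite:
            running = min(running, out[d])
            out[d] = running
    return DecayCurve(expected=out)


def observed_over_expected(cmap: ContactMap, decay: DecayCurve) -> np.ndarray:
    """O/E transform; entries without a defined expected value become NaN."""
    n = cmap.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    E = decay(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = cmap.counts / E
    return oe


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompartmentTrack:
    chrom: str
    resolution_bp: int
    pc1: np.ndarray  # NaN on masked bins
    labels: np.ndarray  # 'A' / 'B' / 'masked'

    def label_of_bp(self, pos: int) -> str:
        return str(self.labels[pos // self.resolution_bp])


def call_compartments(
    cmap: ContactMap,
    gene_density: np.ndarray,
    decay: DecayCurve | None = None,
    use_oe: bool = True,
) -> CompartmentTrack:
    """A/B compartments from the leading eigenvector of the correlation map.

    The balanced matrix is O/E-normalised (raw-count correlation is
    dominated by distance decay; switchable via ``use_oe``), the Pearson
    correlation matrix of its columns is formed, and its first principal
    component taken.  The sign is oriented so Spearman correlation between
    PC1 and gene density is positive; bins with PC1 > 0 are labelled A.
    """
    keep = cmap.unmasked()
    if keep.sum() < 20:
        raise ValueError("fewer than 20 unmasked bins")
    if decay is None:
        decay = fit_decay_curve(cmap)
    mat = observed_over_expected(cmap, decay) if use_oe else cmap.counts.copy()
    sub = mat[np.ix_(keep, keep)]
    sub[~np.isfinite(sub)] = 0.0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr[~np.isfinite(corr)] = 0.0
    eigvals, eigvecs = np.linalg.eigh(corr)
    pc1_sub = eigvecs[:, -1]
    dens = np.asarray(gene_density, dtype=float)[keep]
    rho = stats.spearmanr(pc1_sub, dens).statistic
    if np.isfinite(rho) and rho < 0:
        pc1_sub = -pc1_sub
    pc1 = np.full(cmap.n_bins, np.nan)
    pc1[keep] = pc1_sub
    labels = np.full(cmap.n_bins, "masked", dtype=object)
    labels[keep] = np.where(pc1_sub > 0, "A", "B")
    return CompartmentTrack(
        chrom=cmap.chrom, resolution_bp=cmap.resolution_bp, pc1=pc1, labels=labels
    )


@dataclasses.dataclass
class ABIndexTrack:
    chrom: str
    resolution_bp: int
    ab_index: np.ndarray  # in [-1, 1], NaN where no compartment contact mass


def compute_ab_index(cmap_fine: ContactMap, compartments: CompartmentTrack) -> ABIndexTrack:
    """Signed preference of each fine bin for A versus B territory.

    For each fine bin, ``C_A`` sums its balanced contacts to fine bins
    whose parent coarse bin is labelled A — excluding the bin's own parent
    coarse bin — and likewise ``C_B``; the AB-index is
    ``(C_A - C_B) / (C_A + C_B)``.
    """
    if compartments.resolution_bp % cmap_fine.resolution_bp:
        raise ValueError("compartment resolution must be a multiple of the fine resolution")
    ratio = compartments.resolution_bp // cmap_fine.resolution_bp
    n = cmap_fine.n_bins
    parents = np.arange(n) // ratio
    parents = np.minimum(parents, len(compartments.labels) - 1)
    lab = compartments.labels[parents]
    is_a = lab == "A"
    is_b = lab == "B"
    ab = np.full(n, np.nan)
    keep = cmap_fine.unmasked()
    for i in range(n):
        if not keep[i]:
            continue
        row = cmap_fine.counts[i]
        other = parents != parents[i]
        ca = float(row[is_a & other & keep].sum())
        cb = float(row[is_b & other & keep].sum())
        if ca + cb > 0:
            ab[i] = (ca - cb) / (ca + cb)
    return ABIndexTrack(chrom=cmap_fine.chrom, resolution_bp=cmap_fine.resolution_bp, ab_index=ab)


# ---------------------------------------------------------------------------
# TADs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TADSet:
    chrom: str
    resolution_bp: int
    tads: list[tuple[int, int]]  # half-open bin intervals, sorted, >= 3 bins
    di: np.ndarray
    states: np.ndarray  # -1 upstream-bias, 0 none, +1 downstream-bias
    intactness: np.ndarray | None = None

    @property
    def boundaries(self) -> list[int]:
        return [t[0] for t in self.tads[1:]]

    def tads_bp(self) -> list[tuple[int, int]]:
        r = self.resolution_bp
        return [(s * r, e * r) for s, e in self.tads]

    def containing(self, bin_idx: int) -> int | None:
        for t, (s, e) in enumerate(self.tads):
            if s <= bin_idx < e:
                return t
        return None


def directionality_index(cmap: ContactMap, di_window_bp: int = 2_000_000) -> np.ndarray:
    """Dixon-style signed chi-square contrast of up- vs downstream contacts.

    With A the contact sum to the ``w`` upstream bins, B the downstream sum
    and E = (A+B)/2: ``DI = sign(B - A) ((A-E)^2/E + (B-E)^2/E)``; zero
    when A + B = 0.
    """
    n = cmap.n_bins
    w = di_window_bp // cmap.resolution_bp
    if w < 1 or w >= n:
        warnings.warn("DI window shrunk to fit the chromosome")
        w = max(1, n - 1)
    di = np.zeros(n)
    for i in range(n):
        a = float(cmap.counts[i, max(0, i - w) : i].sum())
        b = float(cmap.counts[i, i + 1 : min(n, i + w + 1)].sum())
        if a + b == 0:
            continue
        e = (a + b) / 2.0
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return di


def _fit_di_hmm(di: np.ndarray, seed: int, n_restarts: int) -> np.ndarray:
    """3-state Gaussian HMM on the DI track; returns -1/0/+1 state labels."""
    from hmmlearn.hmm import GaussianHMM

    # signed log tames the chi-square tails so the three Gaussian states
    # separate by sign (upstream / none / downstream) rather than magnitude
    X = (np.sign(di) * np.log1p(np.abs(di))).reshape(-1, 1)
    best_model, best_score = None, -np.inf
    for r in range(n_restarts):
        model = GaussianHMM(
            n_components=3,
            covariance_type="diag",
            n_iter=200,
            random_state=seed + r,
            min_covar=1e-3,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X)
                score = model.score(X)
        except Exception:
            continue
        if score > best_score:
            best_model, best_score = model, score
    if best_model is None:
        raise RuntimeError("HMM fitting failed on the DI track")
    hidden = best_model.predict(X)
    order = np.argsort(best_model.means_.ravel())
    remap = {order[0]: -1, order[1]: 0, order[2]: 1}
    return np.array([remap[s] for s in hidden])


def call_tads(
    cmap: ContactMap,
    di_window_bp: int = 2_000_000,
    seed: int = 0,
    n_restarts: int = 10,
    min_bins: int = 3,
) -> TADSet:
    """TADs from HMM-segmented directionality index.

    Domain boundaries are placed where the state track switches from the
    upstream-biased state (negative DI, domain end) to the
    downstream-biased state (positive DI, next domain start).  A uniform
    matrix yields no internal boundary and a single whole-chromosome
    domain.  Segments shorter than ``min_bins`` are dropped.
    """
    di = directionality_index(cmap, di_window_bp)
    if np.allclose(di, 0.0) or np.std(di) == 0:
        states = np.zeros(len(di), dtype=int)
    else:
        states = _fit_di_hmm(di, seed, n_restarts)
    n = cmap.n_bins
    boundaries = [0]
    for i in range(1, n):
        prev, cur = states[i - 1], states[i]
        if cur == 1 and prev == -1:
            boundaries.append(i)
    boundaries.append(n)
    tads = [
        (s, e)
        for s, e in zip(boundaries[:-1], boundaries[1:])
        if e - s >= min_bins
    ]
    return TADSet(chrom=cmap.chrom, resolution_bp=cmap.resolution_bp, tads=tads, di=di, states=states)


def tad_intactness(cmap: ContactMap, tads: TADSet, decay: DecayCurve) -> np.ndarray:
    """log2(observed / expected) intra-TAD contact mass per TAD.

    Sums run over intra-TAD bin pairs at distance >= 1; a TAD whose
    expected mass is zero (or undefined) gets NaN with a warning.
    """
    out = np.full(len(tads.tads), np.nan)
    for t, (s, e) in enumerate(tads.tads):
        obs = 0.0
        exp = 0.0
        for i in range(s, e):
            for j in range(i + 1, e):
                obs += cmap.counts[i, j]
                ev = decay.expected[j - i] if j - i < len(decay.expected) else np.nan
                if np.isfinite(ev):
                    exp += ev
        if exp <= 0:
            warnings.warn(f"TAD {t} has zero expected mass; intactness missing")
            continue
        if obs > 0:
            out[t] = float(np.log2(obs / exp))
    tads.intactness = out
    return out


# ---------------------------------------------------------------------------
# TAD cliques
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TADCliqueGraph:
    edges: pd.DataFrame  # tad_i, tad_j, obs, exp, p, q (significant edges only)
    graph: "nx.Graph"
    cliques: list[tuple[int, ...]]  # maximal cliques of size >= 3
    max_clique_size: np.ndarray  # per TAD


def _pair_obs_exp(cmap: ContactMap, decay: DecayCurve, span_a, span_b) -> tuple[float, float]:
    sa, ea = span_a
    sb, eb = span_b
    obs = float(cmap.counts[sa:ea, sb:eb].sum())
    d = np.abs(np.subtract.outer(np.arange(sa, ea), np.arange(sb, eb)))
    ev = decay(d)
    exp = float(np.nansum(ev))
    return obs, exp


def tad_clique_analysis(
    cmap: ContactMap,
    tads: TADSet,
    decay: DecayCurve,
    q_cut: float = 1e-4,
    min_separation: int = 2,
) -> TADCliqueGraph:
    """Cliques of TADs interacting more than the distance decay predicts.

    Non-adjacent TAD pairs (index separation >= 2) are scored by the
    upper-tail Poisson probability of their observed inter-TAD contact sum
    given the decay-model expectation; BH across pairs; edges kept at
    ``q < q_cut`` ("< 0.01%").  Maximal cliques come from Bron-Kerbosch
    with pivoting; each TAD's ``max_clique_size`` is the size of the
    largest maximal clique containing it (1 if isolated).
    """
    nt = len(tads.tads)
    if nt < 2:
        raise ValueError("need at least 2 TADs")
    pairs = []
    for i in range(nt):
        for j in range(i + min_separation, nt):
            obs, exp = _pair_obs_exp(cmap, decay, tads.tads[i], tads.tads[j])
            if exp <= 0:
                continue
            p = float(stats.poisson.sf(np.round(obs) - 1, exp))
            pairs.append((i, j, obs, exp, p))
    df = pd.DataFrame(pairs, columns=["tad_i", "tad_j", "obs", "exp", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = []
    edges = df[df["q"] < q_cut].reset_index(drop=True)
    G = nx.Graph()
    G.add_nodes_from(range(nt))
    G.add_edges_from(zip(edges["tad_i"], edges["tad_j"]))
    cliques, max_size = clique_stats(G, nt)
    return TADCliqueGraph(
        edges=edges, graph=G, cliques=cliques, max_clique_size=max_size
    )


def clique_stats(G: "nx.Graph", n_nodes: int) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Maximal cliques (Bron-Kerbosch with pivoting) and per-node max size.

    Returns the sorted list of maximal cliques of size >= 3 and, for every
    node, the size of the largest maximal clique containing it (1 for an
    isolated node).
    """
    max_size = np.ones(n_nodes, dtype=int)
    cliques = []
    for cl in nx.find_cliques(G):
        for v in cl:
            max_size[v] = max(max_size[v], len(cl))
        if len(cl) >= 3:
            cliques.append(tuple(sorted(cl)))
    return sorted(cliques), max_size


# ---------------------------------------------------------------------------
# promoter-enhancer interactions
# ---------------------------------------------------------------------------

def call_peis(
    cmap: ContactMap,
    tss_bins,
    tad_intervals_bp: list[tuple[int, int]],
    decay: DecayCurve,
    min_dist_bp: int = 60_000,
    q_cut: float = 0.05,
    fallback_span_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Significant promoter-anchored contacts within the promoter's TAD.

    Candidates pair each TSS bin with every other bin of its TAD (or a
    ±1 Mb neighbourhood if the promoter lies outside all TADs, with a
    warning); the upper-tail Poisson p-value against the decay expectation
    is BH-adjusted across candidates, and interactions closer than
    ``min_dist_bp`` are excluded as low-confidence regardless of
    significance.
    """
    res = cmap.resolution_bp
    n = cmap.n_bins
    tad_bins = [(s // res, -(-e // res)) for s, e in tad_intervals_bp]
    rows = []
    for pb in sorted(set(int(b) for b in tss_bins)):
        home = None
        for s, e in tad_bins:
            if s <= pb < e:
                home = (s, e)
                break
        if home is None:
            warnings.warn(f"promoter bin {pb} outside all TADs; using ±{fallback_span_bp} bp")
            span = fallback_span_bp // res
            home = (max(0, pb - span), min(n, pb + span + 1))
        for j in range(home[0], min(home[1], n)):
            if j == pb:
                continue
            exp = decay.expected[abs(j - pb)] if abs(j - pb) < len(decay.expected) else np.nan
            if not np.isfinite(exp) or exp <= 0:
                continue
            obs = float(cmap.counts[pb, j])
            p = float(stats.poisson.sf(np.round(obs) - 1, exp))
            rows.append((pb, j, abs(j - pb) * res, obs, exp, p))
    df = pd.DataFrame(
        rows, columns=["promoter_bin", "enhancer_bin", "distance_bp", "obs", "exp", "p"]
    )
    if not len(df):
        df["q"] = []
        return df
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df[(df["q"] < q_cut) & (df["distance_bp"] >= min_dist_bp)].reset_index(drop=True)
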