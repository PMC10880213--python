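"""Synthetic data with planted, recoverable truth.

Every downstream stage of the toolkit is exercised on data produced here:
two-population genotypes with a tunable fixation index and planted sweep
regions, Hi-C contact maps with distance decay, compartment checkerboard,
TAD blocks, TAD cliques and promoter-enhancer loops, and a TPM expression
table coupled to the planted structures.

Genotypes follow the Balding-Nichols model: an ancestral allele frequency
``p ~ Uniform(0.05, 0.95)`` and per-population frequencies drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F`` the target FST, so the weighted
Weir-Cockerham estimator has a known expectation to recover.  Sweeps are
modelled as captive-population frequency shifts toward fixation, the signal
the downstream scan filters on.  Contact counts are Poisson around a
multiplicative expected model, matching the Poisson significance tests used
by the structure callers.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import field

import numpy as np
import pandas as pd

from .genio import ContactMap, GenotypePanel, gene_table

# per-operation stream tags so each generator is deterministic on its own
_GENO, _HIC, _EXPR, _DIV = 11, 23, 37, 53


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults used throughout.

    The genotype defaults mirror the matched design the analysis targets:
    11 captive vs 11 wild diploid individuals, 20,000 SNPs on a 20-Mb
    chromosome, target FST 0.1.
    """

    seed: int = 0
    # genotypes
    n_captive: int = 11
    n_wild: int = 11
    n_snps: int = 20_000
    target_fst: float = 0.1
    sweep_regions: list[tuple] = field(default_factory=list)  # (chrom, start, end, shift)
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 20_000_000})
    generation_labels: dict[str, str] | None = None
    # contact map
    resolution_bp: int = 100_000
    n_compartment_blocks: int = 10
    compartment_strength: float = 0.6
    tad_sizes_bins: list[int] = field(default_factory=list)
    tad_fold: float = 3.0
    clique_groups: list = field(default_factory=list)  # sets of TAD indices
    clique_fold: float = 8.0
    loop_anchors: list[tuple] = field(default_factory=list)  # (promoter_bin, enhancer_bin, fold)
    decay_exponent: float = 1.0
    base_count: float = 300.0
    # expression / annotation
    n_genes: int = 500
    n_expr_samples: int = 6
    expr_log2_sd: float = 1.0
    go_n_terms: int = 20
    shifted_term: str | None = None
    expression_shift_log2: float = 0.0
    structure_shift_log2: float = 0.0
    diversity_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst <= 0.5):
            raise ValueError("target_fst must lie in [0, 0.5]")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom}")
        for chrom, start, end, _shift in self.sweep_regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep region on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"sweep region {chrom}:{start}-{end} outside chromosome")


@dataclasses.dataclass
class TruthSet:
    """Queryable record of everything the simulator planted.

    All regions are 0-based half-open; Hi-C entries are in bin units of the
    generating resolution.
    """

    true_sweeps: list[tuple] = field(default_factory=list)
    compartment_labels: np.ndarray | None = None  # per-bin 'A'/'B'
    tad_boundaries: list[int] = field(default_factory=list)  # bin indices
    tad_intervals: list[tuple[int, int]] = field(default_factory=list)  # half-open bins
    clique_membership: dict[int, int] = field(default_factory=dict)  # TAD idx -> group
    loops: list[tuple] = field(default_factory=list)
    expression_effects: dict[str, str] = field(default_factory=dict)  # gene -> up/down

    def sweeps_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e, _ in self.true_sweeps if c == chrom]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _scatter_positions(rng, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.3) + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_two_pop_genotypes(config: SimulationConfig) -> tuple[GenotypePanel, TruthSet]:
    """Draw a captive/wild genotype panel under the Balding-Nichols model."""
    rng = np.random.default_rng([config.seed, _GENO])
    F = config.target_fst
    if F <= 0:
        warnings.warn("target_fst <= 0; using F = 1e-6")
        F = 1e-6

    total_len = sum(config.chrom_lengths.values())
    chroms, positions = [], []
    remaining = config.n_snps
    items = list(config.chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        n_here = remaining if i == len(items) - 1 else int(round(config.n_snps * length / total_len))
        n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        pos = _scatter_positions(rng, length, n_here)
        chroms.extend([chrom] * n_here)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    n = len(pos_all)

    p_anc = rng.uniform(0.05, 0.95, size=n)
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    p_cap = rng.beta(a, b)
    p_wild = rng.beta(a, b)

    chrom_arr = np.array(chroms)
    for chrom, start, end, shift in config.sweep_regions:
        inside = (chrom_arr == chrom) & (pos_all - 1 >= start) & (pos_all - 1 < end)
        p_cap[inside] = np.clip(p_cap[inside] + shift, 0.0, 1.0)

    g_cap = rng.binomial(2, p_cap, size=(config.n_captive, n))
    g_wild = rng.binomial(2, p_wild, size=(config.n_wild, n))

    cap_ids = [f"C{i:02d}" for i in range(1, config.n_captive + 1)]
    wild_ids = [f"W{i:02d}" for i in range(1, config.n_wild + 1)]
    population = {s: "captive" for s in cap_ids} | {s: "wild" for s in wild_ids}
    sites = pd.DataFrame(
        {"chrom": chrom_arr, "pos": pos_all, "ref": "A", "alt": "G"}
    )
    panel = GenotypePanel(
        sample_ids=cap_ids + wild_ids,
        population=population,
        sites=sites,
        genotypes=np.vstack([g_cap, g_wild]).astype(np.int8),
        generation=dict(config.generation_labels) if config.generation_labels else None,
    )
    truth = TruthSet(true_sweeps=list(config.sweep_regions))
    return panel, truth


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def _tile_tads(tad_sizes: list[int], n_bins: int) -> list[tuple[int, int]]:
    """Cycle the size list across the chromosome; last domain truncates."""
    out, pos, i = [], 0, 0
    while pos < n_bins:
        size = tad_sizes[i % len(tad_sizes)]
        out.append((pos, min(pos + size, n_bins)))
        pos += size
        i += 1
    return out


def expected_contact_matrix(config: SimulationConfig, chrom: str | None = None) -> tuple[np.ndarray, TruthSet]:
    """Noise-free expected contact model plus the planted truth."""
    if chrom is None:
        chrom = next(iter(config.chrom_lengths))
    length = config.chrom_lengths[chrom]
    n_bins = math.ceil(length / config.resolution_bp)
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    E = config.base_count * (d + 1.0) ** (-config.decay_exponent)

    truth = TruthSet()
    if config.n_compartment_blocks > 0:
        block = max(1, n_bins // config.n_compartment_blocks)
        labels = np.where((np.arange(n_bins) // block) % 2 == 0, "A", "B")
        s = config.compartment_strength
        same = np.equal.outer(labels, labels)
        E = E * np.where(same, 1.0 + s, 1.0 - s)
        truth.compartment_labels = labels

    if config.tad_sizes_bins:
        tads = _tile_tads(config.tad_sizes_bins, n_bins)
        truth.tad_intervals = tads
        truth.tad_boundaries = [t[0] for t in tads[1:]]
        intra = np.zeros((n_bins, n_bins), dtype=bool)
        for s0, e0 in tads:
            intra[s0:e0, s0:e0] = True
        E = E * np.where(intra, config.tad_fold, 1.0)
        for gid, group in enumerate(config.clique_groups):
            group = sorted(group)
            for t in group:
                if t >= len(tads):
                    raise ValueError(f"clique group references TAD {t} of {len(tads)}")
                truth.clique_membership[t] = gid
            for ti in group:
                for tj in group:
                    if ti == tj:
                        continue
                    s0, e0 = tads[ti]
                    s1, e1 = tads[tj]
                    E[s0:e0, s1:e1] *= config.clique_fold

    for pbin, ebin, fold in config.loop_anchors:
        E[pbin, ebin] *= fold
        if pbin != ebin:
            E[ebin, pbin] *= fold
        truth.loops.append((pbin, ebin, fold))
    return E, truth


def simulate_contact_map(config: SimulationConfig, chrom: str | None = None) -> tuple[ContactMap, TruthSet]:
    """Poisson-sampled symmetric contact map around the expected model."""
    if chrom is None:
        chrom = next(iter(config.chrom_lengths))
    rng = np.random.default_rng([config.seed, _HIC])
    E, truth = expected_contact_matrix(config, chrom)
    n = E.shape[0]
    upper = rng.poisson(np.triu(E))
    counts = np.triu(upper) + np.triu(upper, 1).T
    masked = set(np.where(counts.sum(axis=1) == 0)[0].tolist())
    cmap = ContactMap(
        chrom=chrom,
        resolution_bp=config.resolution_bp,
        counts=counts.astype(float),
        masked_bins=masked,
    )
    return cmap, truth


# ---------------------------------------------------------------------------
# expression and annotation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneStructureTable:
    """Per-gene integration substrate: expression, GO terms and the four
    chromatin factors (AB-index, TAD intactness, clique size, enhancer
    count)."""

    genes: pd.DataFrame  # gene_id-indexed, factor + tpm columns
    tpm: pd.DataFrame  # samples x genes, columns sum to 1e6
    go_map: dict[str, set[str]]


def simulate_expression_and_annotation(
    config: SimulationConfig, structures: TruthSet | None = None
) -> tuple[GeneStructureTable, TruthSet]:
    """Genes with synthetic GO terms, chromatin factors and TPM values.

    Baseline log2 expression is Normal(5, ``expr_log2_sd``) per gene with
    Normal(0, 0.3) per-sample noise; the default between-gene spread is
    deliberately narrow so a planted twofold shift on a ~50-gene term is an
    unambiguous signal.  ``structure_shift_log2`` (negative) is applied to
    genes sitting in B territory or in large cliques; ``shifted_term`` genes
    receive ``expression_shift_log2`` and, when that shift is non-zero, are
    additionally pushed into the regulated class of all four factors so the
    planted term is recoverable end-to-end.
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng([config.seed, _EXPR])
    chrom = next(iter(config.chrom_lengths))
    length = config.chrom_lengths[chrom]
    truth = structures if structures is not None else TruthSet()

    starts = np.sort(rng.choice(max(1, length - 5000), size=config.n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_genes)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    genes = gene_table(
        [
            (gid, chrom, int(s), int(s) + 5000, str(st))
            for gid, s, st in zip(gene_ids, starts, strands)
        ]
    ).set_index("gene_id")

    terms = [f"GO:S{i:04d}" for i in range(config.go_n_terms)]
    go_map: dict[str, set[str]] = {t: set() for t in terms}
    for gid in gene_ids:
        n_terms = rng.integers(1, 4)
        for t in rng.choice(terms, size=n_terms, replace=False):
            go_map[t].add(gid)
    go_map = {t: g for t, g in go_map.items() if g}

    # chromatin factors, anchored to planted truth where available
    if truth.compartment_labels is not None:
        bins = np.minimum(
            genes["tss"].to_numpy() // config.resolution_bp,
            len(truth.compartment_labels) - 1,
        )
        base_ab = np.where(truth.compartment_labels[bins] == "A", 0.4, -0.4)
    else:
        base_ab = np.zeros(config.n_genes)
    genes["ab_index"] = np.clip(base_ab + rng.normal(0, 0.2, config.n_genes), -1, 1)
    genes["tad_intactness"] = rng.normal(0.0, 0.5, config.n_genes)
    if truth.tad_intervals:
        tads = truth.tad_intervals
        tss_bins = genes["tss"].to_numpy() // config.resolution_bp
        clique_size = np.ones(config.n_genes, dtype=float)
        sizes_by_group: dict[int, int] = {}
        for t, g in truth.clique_membership.items():
            sizes_by_group[g] = sizes_by_group.get(g, 0) + 1
        for i, b in enumerate(tss_bins):
            for ti, (s0, e0) in enumerate(tads):
                if s0 <= b < e0:
                    gid_ = truth.clique_membership.get(ti)
                    clique_size[i] = sizes_by_group.get(gid_, 1)
                    break
        genes["clique_size"] = clique_size
    else:
        genes["clique_size"] = rng.integers(1, 4, config.n_genes).astype(float)
    genes["enhancer_count"] = rng.poisson(3.0, config.n_genes).astype(float)

    log2_expr = rng.normal(5.0, config.expr_log2_sd, config.n_genes)
    if config.structure_shift_log2 != 0.0:
        adverse = (genes["ab_index"].to_numpy() < 0) | (
            genes["clique_size"].to_numpy() >= np.quantile(genes["clique_size"], 0.9)
        )
        log2_expr = log2_expr + config.structure_shift_log2 * adverse
        for gid in np.array(gene_ids)[adverse]:
            truth.expression_effects[gid] = "down" if config.structure_shift_log2 < 0 else "up"

    if config.shifted_term is not None:
        members = sorted(go_map.get(config.shifted_term, set()))
        idx = genes.index.get_indexer(members)
        log2_expr[idx] = log2_expr[idx] + config.expression_shift_log2
        if config.expression_shift_log2 != 0.0:
            direction = "down" if config.expression_shift_log2 < 0 else "up"
            for gid in members:
                truth.expression_effects[gid] = direction
            # plant the members in the regulated class of every factor
            genes.loc[members, "ab_index"] = -1.0 + rng.uniform(0, 0.02, len(members))
            genes.loc[members, "tad_intactness"] = -3.0 + rng.uniform(0, 0.02, len(members))
            genes.loc[members, "clique_size"] = 12.0
            genes.loc[members, "enhancer_count"] = 0.0

    noise = rng.normal(0.0, 0.3, size=(config.n_expr_samples, config.n_genes))
    raw = np.power(2.0, log2_expr[None, :] + noise)
    tpm_mat = raw / raw.sum(axis=1, keepdims=True) * 1e6
    tpm = pd.DataFrame(
        tpm_mat,
        index=[f"S{i:02d}" for i in range(1, config.n_expr_samples + 1)],
        columns=gene_ids,
    )
    genes["tpm"] = tpm.mean(axis=0).to_numpy()
    return GeneStructureTable(genes=genes, tpm=tpm, go_map=go_map), truth


def simulate_window_diversity_track(
    config: SimulationConfig,
    truth: TruthSet,
    window_bp: int = 40_000,
    step_bp: int = 20_000,
    baseline: float = 1e-3,
) -> pd.DataFrame:
    """Windowed nucleotide-diversity track coupled to the compartments.

    ``diversity_coupling`` adds that amount of diversity to windows whose
    midpoint lies in a B-labelled bin (closed chromatin carrying more
    variation), the planted effect the integration stage must recover.
    """
    rng = np.random.default_rng([config.seed, _DIV])
    chrom = next(iter(config.chrom_lengths))
    length = config.chrom_lengths[chrom]
    rows = []
    for start in range(0, length, step_bp):
        end = min(start + window_bp, length)
        mid_bin = ((start + end) // 2) // config.resolution_bp
        pi = baseline * (1.0 + rng.normal(0, 0.25))
        if truth.compartment_labels is not None:
            mid_bin = min(mid_bin, len(truth.compartment_labels) - 1)
            if truth.compartment_labels[mid_bin] == "B":
                pi += config.diversity_coupling
        rows.append((chrom, start, end, max(pi, 0.0)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi_captive"])
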