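"""Integration of diversity, chromatin structure and expression.

Three questions: does windowed nucleotide diversity track the structural
layers (Spearman correlations against PC1, AB-index, TAD intactness and
clique size); which GO terms have their structurally "regulated" genes
expressed differently from the genomic background in all four factors; and
which individual genes sit simultaneously in the extreme class of every
factor.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GeneStructureTable

FACTORS = ("ab_index", "tad_intactness", "clique_size", "enhancer_count")
# regulated class direction per factor: large cliques repress, the others
# regulate when low
_FACTOR_LOW = {"ab_index": True, "tad_intactness": True, "clique_size": False, "enhancer_count": True}


@dataclasses.dataclass
class CorrelationResult:
    layer: str
    n_pairs: int
    spearman_r: float
    p: float


def _windows_to_bins(
    windows: pd.DataFrame, value_col: str, resolution_bp: int, n_bins: int, chrom: str
) -> np.ndarray:
    """Overlap-weighted mean of window values per bin of one chromosome."""
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    sub = windows[(windows["chrom"] == chrom) & windows[value_col].notna()]
    for row in sub.itertuples(index=False):
        val = getattr(row, value_col)
        b0 = row.start // resolution_bp
        b1 = min((row.end - 1) // resolution_bp, n_bins - 1)
        for b in range(b0, b1 + 1):
            lo = max(row.start, b * resolution_bp)
            hi = min(row.end, (b + 1) * resolution_bp)
            if hi > lo:
                num[b] += val * (hi - lo)
                den[b] += hi - lo
    with np.errstate(invalid="ignore"):
        out = num / den
    return out


def correlate_diversity_with_structure(
    windows: pd.DataFrame,
    layer_values: np.ndarray,
    resolution_bp: int,
    chrom: str,
    layer: str = "pc1",
    value_col: str = "pi_captive",
) -> CorrelationResult:
    """Spearman correlation between windowed diversity and a structure track.

    Window values are mapped onto the track's bins by overlap-weighted
    mean; the rank correlation uses exact tie handling and a two-sided p.
    Fewer than 10 mapped pairs raise; zero rank variance returns NaN with a
    warning.
    """
    layer_values = np.asarray(layer_values, dtype=float)
    binned = _windows_to_bins(windows, value_col, resolution_bp, len(layer_values), chrom)
    ok = np.isfinite(binned) & np.isfinite(layer_values)
    if ok.sum() < 10:
        raise ValueError(f"only {int(ok.sum())} mapped pairs; need at least 10")
    x, y = binned[ok], layer_values[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("zero rank variance; correlation undefined")
        return CorrelationResult(layer, int(ok.sum()), np.nan, np.nan)
    res = stats.spearmanr(x, y)
    return CorrelationResult(layer, int(ok.sum()), float(res.statistic), float(res.pvalue))


def regulated_classes(
    genes: pd.DataFrame, fraction: float = 0.25, factors=FACTORS
) -> dict[str, pd.Index]:
    """Per-factor regulated gene class by inclusive percentile threshold.

    Bottom ``fraction`` for AB-index, intactness and enhancer count; top
    ``fraction`` for clique size.
    """
    out = {}
    for f in factors:
        vals = genes[f]
        if _FACTOR_LOW[f]:
            thr = np.quantile(vals.dropna(), fraction)
            out[f] = genes.index[vals <= thr]
        else:
            thr = np.quantile(vals.dropna(), 1 - fraction)
            out[f] = genes.index[vals >= thr]
    return out


def go_expression_vs_background(
    table: GeneStructureTable,
    go_map: dict[str, set[str]] | None = None,
    regulated_fraction: float = 0.25,
    alpha: float = 0.01,
    min_class_genes: int = 3,
) -> pd.DataFrame:
    """Per-term, per-factor rank-sum tests of member TPM vs the background.

    For each GO term and each of the four chromatin factors, the TPM of the
    term's genes lying in that factor's regulated class is compared with
    the all-gene background by a two-sided Wilcoxon rank-sum test; the
    direction is the sign of the median difference.  A term is retained iff
    all four factor tests are evaluable (>= ``min_class_genes`` genes) and
    reach ``p <= alpha``.
    """
    genes = table.genes
    go_map = go_map if go_map is not None else table.go_map
    classes = regulated_classes(genes, regulated_fraction)
    background = genes["tpm"].to_numpy()
    bg_median = float(np.median(background))
    rows = []
    for term, members in sorted(go_map.items()):
        members = [g for g in members if g in genes.index]
        retained = True
        term_rows = []
        for f in FACTORS:
            in_class = [g for g in members if g in set(classes[f])]
            if len(in_class) < min_class_genes:
                term_rows.append((term, f, len(in_class), np.nan, "na"))
                retained = False
                continue
            vals = genes.loc[in_class, "tpm"].to_numpy()
            p = float(stats.mannwhitneyu(vals, background, alternative="two-sided").pvalue)
            direction = "down" if np.median(vals) < bg_median else "up"
            term_rows.append((term, f, len(in_class), p, direction))
            if p > alpha:
                retained = False
        for r in term_rows:
            rows.append(r + (retained,))
    return pd.DataFrame(
        rows, columns=["term_id", "factor", "n_genes", "p", "direction", "retained"]
    )


def retained_terms(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-factor table to one row per retained term."""
    kept = results[results["retained"]]
    rows = []
    for term, sub in kept.groupby("term_id"):
        downs = (sub["direction"] == "down").sum()
        rows.append((term, "down" if downs >= len(sub) / 2 else "up"))
    return pd.DataFrame(rows, columns=["term_id", "direction"])


def multifactor_gene_filter(
    table: GeneStructureTable | pd.DataFrame,
    top_clique: float = 0.05,
    bottom_others: float = 0.05,
) -> list[str]:
    """Genes extreme in all four factors simultaneously.

    Retains genes in the top ``top_clique`` fraction of clique size AND the
    bottom ``bottom_others`` fraction of AB-index, TAD intactness and
    enhancer count; thresholds are inclusive, genes with any missing factor
    are excluded.
    """
    genes = table.genes if isinstance(table, GeneStructureTable) else table
    complete = genes.dropna(subset=list(FACTORS))
    if len(complete) < 20:
        raise ValueError(f"only {len(complete)} genes with complete factors; need >= 20")
    clique_thr = np.quantile(complete["clique_size"], 1 - top_clique)
    mask = complete["clique_size"] >= clique_thr
    for f in ("ab_index", "tad_intactness", "enhancer_count"):
        thr = np.quantile(complete[f], bottom_others)
        mask &= complete[f] <= thr
    return sorted(complete.index[mask])


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir) -> dict:
    """End-to-end synthetic run: simulate, match, scan, GO, Hi-C, integrate.

    ``config`` is a :class:`~shortadapt.simdata.SimulationConfig` or a dict
    of its fields.  Writes the stage artifacts plus a JSON run report (per
    stage in/out counts and thresholds) under ``out_dir`` and returns the
    report.
    """
    from . import __version__, cohort, gostats, hic, simdata, sweep
    from .genio import write_genotypes_vcf, write_region_bed

    if isinstance(config, dict):
        config = simdata.SimulationConfig(**config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "tail": 0.05,
            "snp_diff": 0.6,
            "go_alpha": 0.01,
            "clique_q": 1e-4,
            "pei_min_dist_bp": 60_000,
            "resolution_min_contacts": 1000,
            "resolution_min_fraction": 0.80,
        },
        "stages": {},
    }

    panel, truth = simdata.simulate_two_pop_genotypes(config)
    write_genotypes_vcf(panel, out / "genotypes.vcf")
    report["stages"]["simulate"] = {"n_samples": panel.n_samples, "n_snps": panel.n_sites}

    proj = cohort.compute_pca(panel, k=3)
    k = min(config.n_captive, config.n_wild)
    match = cohort.match_wild_subset(
        proj,
        [s for s in panel.sample_ids if panel.population[s] == "captive"],
        [s for s in panel.sample_ids if panel.population[s] == "wild"],
        k=k,
    )
    report["stages"]["match"] = {
        "n_subsets_evaluated": match.n_subsets_evaluated,
        "score": match.score,
        "chosen_wild": list(match.chosen_wild),
    }

    windows = sweep.window_stats(panel, config.chrom_lengths)
    snps = sweep.snp_frequency_table(panel)
    regions = sweep.identify_selected_regions(windows, snps)
    robust = regions[regions["robust"] & (regions["direction"] == "captive")]
    windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    write_region_bed(
        [(r.chrom, r.start, r.end, r.direction) for r in regions.itertuples(index=False)],
        out / "selected_regions.bed",
    )
    report["stages"]["scan"] = {
        "n_windows": len(windows),
        "n_selected": len(regions),
        "n_robust_captive": len(robust),
    }

    table, truth = simdata.simulate_expression_and_annotation(config, truth)
    gstats = gostats.gene_window_stats(windows, table.genes)
    strength = gostats.term_selection_strength(gstats, table.go_map, n_perm=1000, seed=config.seed)
    strength.to_csv(out / "go_selection_strength.tsv", sep="\t", index=False)
    report["stages"]["gostats"] = {
        "n_terms_tested": len(strength),
        "n_significant": int(strength["significant"].sum()),
    }

    cmap, hic_truth = simdata.simulate_contact_map(config)
    balanced = hic.kr_balance(cmap)
    decay = hic.fit_decay_curve(balanced)
    gene_density = np.zeros(balanced.n_bins)
    for tss in table.genes["tss"]:
        gene_density[min(tss // config.resolution_bp, balanced.n_bins - 1)] += 1
    comp = hic.call_compartments(balanced, gene_density, decay)
    tads = hic.call_tads(balanced, seed=config.seed)
    intact = hic.tad_intactness(balanced, tads, decay)
    cliques = hic.tad_clique_analysis(balanced, tads, decay)
    report["stages"]["hic"] = {
        "n_bins": balanced.n_bins,
        "n_A": int((comp.labels == "A").sum()),
        "n_B": int((comp.labels == "B").sum()),
        "n_tads": len(tads.tads),
        "n_cliques": len(cliques.cliques),
        "mean_intactness": float(np.nanmean(intact)) if len(intact) else None,
    }

    div = simdata.simulate_window_diversity_track(config, hic_truth)
    corr = correlate_diversity_with_structure(
        div, comp.pc1, config.resolution_bp, cmap.chrom, layer="pc1"
    )
    go_res = go_expression_vs_background(table)
    kept = retained_terms(go_res)
    go_res.to_csv(out / "go_expression.tsv", sep="\t", index=False)
    report["stages"]["integrate"] = {
        "pc1_spearman_r": corr.spearman_r,
        "pc1_spearman_p": corr.p,
        "n_terms_retained": len(kept),
        "retained": kept.to_dict("records"),
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
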