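"""Readers/writers and core containers shared by every analysis stage.

Coordinate conventions are enforced here once and relied on everywhere
else: VCF positions are 1-based; every internal interval (BED regions,
windows, Hi-C bins, gene bodies) is 0-based half-open; Hi-C bin ``i`` of a
map at resolution ``r`` covers ``[i*r, (i+1)*r)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel for a missing genotype in the dosage matrix
MISSING = -1


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypePanel:
    """Diploid biallelic genotypes for a set of labelled samples.

    ``genotypes`` holds alt-allele dosages (0/1/2) with ``-1`` for missing,
    shaped ``(n_samples, n_sites)``.  ``sites`` is a DataFrame with columns
    ``chrom, pos, ref, alt`` (``pos`` 1-based, strictly increasing within a
    chromosome).  ``population`` maps each sample id to a population label
    (e.g. ``captive`` / ``wild``); ``generation`` is an optional second
    grouping (e.g. F1..F5).
    """

    sample_ids: list[str]
    population: dict[str, str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    generation: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        missing = set(self.sample_ids) - set(self.population)
        if missing:
            raise ValueError(f"samples without population label: {sorted(missing)}")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def group_indices(self, by: str = "population") -> dict[str, np.ndarray]:
        """Row indices per group label; ``by`` is ``population`` or ``generation``."""
        if by == "population":
            labels = self.population
        elif by == "generation":
            if self.generation is None:
                raise ValueError("panel has no generation labels")
            labels = self.generation
        else:
            raise ValueError(f"unknown grouping {by!r}")
        unlabeled = [s for s in self.sample_ids if s not in labels]
        if unlabeled:
            raise ValueError(f"samples without {by} label: {unlabeled}")
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.sample_ids):
            out.setdefault(labels[s], []).append(i)
        return {g: np.array(ix, dtype=int) for g, ix in sorted(out.items())}

    def subset_samples(self, ids) -> "GenotypePanel":
        idx = self.sample_indices(ids)
        return GenotypePanel(
            sample_ids=list(ids),
            population={s: self.population[s] for s in ids},
            sites=self.sites.copy(),
            genotypes=self.genotypes[idx],
            generation=(
                {s: self.generation[s] for s in ids if s in self.generation}
                if self.generation
                else None
            ),
        )

    def chrom_span(self) -> dict[str, int]:
        """Largest observed position per chromosome (a lower bound on length)."""
        return {c: int(s["pos"].max()) for c, s in self.sites.groupby("chrom", sort=False)}


def read_genotypes_vcf(
    path,
    population_map: dict[str, str],
    min_gq: int = 30,
    min_site_depth: int = 50,
    depth_mode: str = "site",
    generation_map: dict[str, str] | None = None,
) -> GenotypePanel:
    """Load biallelic SNPs from a VCF into a :class:`GenotypePanel`.

    Genotypes with GQ below ``min_gq`` are set to missing; sites whose
    INFO/DP (summed cohort depth) is below ``min_site_depth`` are dropped.
    ``depth_mode='genotype'`` instead applies the depth cut per sample via
    FORMAT/DP.  Multi-allelic and non-SNP records are dropped with a logged
    count.  Records lacking the relevant annotation pass the corresponding
    filter.
    """
    from cyvcf2 import VCF

    if depth_mode not in ("site", "genotype"):
        raise ValueError("depth_mode must be 'site' or 'genotype'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = set(population_map) - set(samples)
    if unknown:
        raise ValueError(f"population map names samples absent from VCF: {sorted(unknown)}")
    unlabeled = set(samples) - set(population_map)
    if unlabeled:
        raise ValueError(f"VCF samples without population label: {sorted(unlabeled)}")

    rows = []
    dosages = []
    n_dropped_nonsnp = 0
    n_dropped_depth = 0
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_dropped_nonsnp += 1
                continue
            dp = v.INFO.get("DP")
            if depth_mode == "site" and dp is not None and dp < min_site_depth:
                n_dropped_depth += 1
                continue
            gt = v.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            gq = v.gt_quals
            if gq is not None:
                gq = np.asarray(gq, dtype=float)
                bad = np.isfinite(gq) & (gq >= 0) & (gq < min_gq)
                dos[bad] = MISSING
            if depth_mode == "genotype":
                fmt_dp = v.format("DP")
                if fmt_dp is not None:
                    dos[np.asarray(fmt_dp).ravel() < min_site_depth] = MISSING
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
            dosages.append(dos.astype(np.int8))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
    if n_dropped_nonsnp:
        log.info("dropped %d multi-allelic/non-SNP records", n_dropped_nonsnp)
    if n_dropped_depth:
        log.info("dropped %d sites below depth %d", n_dropped_depth, min_site_depth)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    geno = (
        np.array(dosages, dtype=np.int8).T
        if dosages
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypePanel(
        sample_ids=samples,
        population=dict(population_map),
        sites=sites,
        genotypes=geno,
        generation=dict(generation_map) if generation_map else None,
    )


def write_genotypes_vcf(panel: GenotypePanel, path, site_depth: int = 1000) -> None:
    """Write a panel as a minimal VCF v4.2 (GT-only FORMAT, INFO/DP set).

    ``site_depth`` is written as INFO/DP on every record so that re-reading
    with the default depth filter keeps all sites.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, site in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join(gt_strings[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t"
                f"DP={site_depth}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContactMap:
    """A per-chromosome symmetric binned contact matrix."""

    chrom: str
    resolution_bp: int
    counts: np.ndarray
    balanced: bool = False
    bias_vector: np.ndarray | None = None
    masked_bins: set[int] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.masked_bins)] = False
        return keep


def read_contact_map(path, chrom: str, resolution_bp: int, n_bins: int) -> ContactMap:
    """Read whitespace triplets ``chrom bin_i bin_j count`` into a dense map.

    Duplicate ``(i, j)`` entries are summed with a warning; bins outside
    ``[0, n_bins)`` or negative counts raise.  All-zero rows are masked.
    """
    mat = np.zeros((n_bins, n_bins))
    seen: set[tuple[int, int]] = set()
    dup = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 fields, got {len(parts)}")
            c, i, j, count = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c != chrom:
                continue
            if count < 0:
                raise ValueError(f"{path}:{line_no}: negative count {count}")
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ValueError(f"{path}:{line_no}: bin out of range for n_bins={n_bins}")
            key = (min(i, j), max(i, j))
            if key in seen:
                dup += 1
            seen.add(key)
            mat[i, j] += count
            if i != j:
                mat[j, i] += count
    if dup:
        warnings.warn(f"{dup} duplicate contact entries summed in {path}")
    masked = set(np.where(mat.sum(axis=1) == 0)[0].tolist())
    return ContactMap(chrom=chrom, resolution_bp=resolution_bp, counts=mat, masked_bins=masked)


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write the upper triangle (incl. diagonal) as triplet text."""
    with open(path, "w") as fh:
        n = cmap.n_bins
        for i in range(n):
            for j in range(i, n):
                v = cmap.counts[i, j]
                if v != 0:
                    fh.write(f"{cmap.chrom}\t{i}\t{j}\t{v:g}\n")


# ---------------------------------------------------------------------------
# regions, genes, tables
# ---------------------------------------------------------------------------

def write_region_bed(regions, path) -> None:
    """Write ``(chrom, start, end[, name[, score]])`` tuples as sorted BED."""
    rows = []
    for reg in regions:
        chrom, start, end = reg[0], int(reg[1]), int(reg[2])
        if start >= end:
            raise ValueError(f"empty/inverted region {chrom}:{start}-{end}")
        name = reg[3] if len(reg) > 3 else "."
        score = reg[4] if len(reg) > 4 else 0
        rows.append((chrom, start, end, name, score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def read_region_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                (f[0], int(f[1]), int(f[2]))
                + ((f[3],) if len(f) > 3 else ())
                + ((float(f[4]),) if len(f) > 4 else ())
            )
    return out


def gene_table(records) -> pd.DataFrame:
    """Build the standard gene annotation table.

    ``records`` yields ``(gene_id, chrom, start, end, strand)``; the TSS is
    derived from the strand (``start`` for ``+``, ``end - 1`` for ``-``).
    """
    df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene with start >= end")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def read_gff3_genes(path) -> pd.DataFrame:
    """Extract gene records from a GFF3 file (other feature types ignored)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}"))
            rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return gene_table(rows)


def read_go_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> term -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], comment="#")
    out: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        out.setdefault(term, set()).add(gene)
    return out


def write_go_map(go_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(go_map):
            for gene in sorted(go_map[term]):
                fh.write(f"{gene}\t{term}\n")


def read_tpm_table(path) -> pd.DataFrame:
    """TSV with a ``gene_id`` column and one column per sample (TPM units)."""
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def read_population_map(path) -> dict[str, str]:
    """Two-column TSV (sample_id, population)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], comment="#")
    return dict(zip(df["sample"], df["population"]))
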