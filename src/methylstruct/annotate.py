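"""Marker-to-gene assignment and gene-set enrichment.

Markers with genomic coordinates are assigned to the gene body containing
them (exon or intron category); intergenic markers are linked to the
nearest gene within a 5 kb window measured from the gene-body boundary.
Markers inside overlapping genes, or equidistant from two nearest genes,
are dropped as ambiguous — only single-hit loci are retained.  Enrichment
of a study gene set against a user-supplied gene-to-term map uses the
one-sided Fisher exact (hypergeometric) test with Benjamini-Hochberg FDR,
keeping terms with q < 0.05 that are represented by at least three study
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneAnnotation",
    "load_gff",
    "assign_genes",
    "load_term_map",
    "fisher_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class Gene:
    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    exons: list[tuple[int, int]]


@dataclass
class GeneAnnotation:
    """Gene bodies and exon intervals per contig, loaded from GFF3."""

    genes: dict[str, Gene]

    def __post_init__(self) -> None:
        by_contig: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            if g.start > g.end or g.start < 1:
                raise ValueError(f"gene {g.gene_id!r} has invalid coordinates")
            by_contig.setdefault(g.contig, []).append(g)
        for lst in by_contig.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._by_contig = by_contig

    def contig_genes(self, contig: str) -> list[Gene]:
        return self._by_contig.get(contig, [])


def load_gff(path: str | Path) -> GeneAnnotation:
    """Parse a GFF3 file into gene bodies with their exon intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, Gene] = {}
    for feat in db.features_of_type("gene"):
        exons = [
            (e.start, e.end) for e in db.children(feat, featuretype="exon")
        ]
        gid = feat.id
        if gid in genes:
            raise ValueError(f"duplicated gene ID {gid!r} in GFF")
        genes[gid] = Gene(
            gene_id=gid, contig=feat.seqid, start=feat.start, end=feat.end, exons=exons
        )
    return GeneAnnotation(genes=genes)


def assign_genes(
    marker_coords: dict[str, tuple[str, int]],
    annotation: GeneAnnotation,
    window: int = 5000,
) -> pd.DataFrame:
    """Assign each marker to at most one gene.

    Categories: ``exon`` / ``intron`` (inside a single gene body),
    ``intergenic_linked`` (nearest gene within ``window`` bp of a gene
    boundary), ``ambiguous`` (overlapping genes, or a distance tie —
    dropped), ``unassigned``.  Deterministic and independent of marker
    order.  Returns a frame with columns marker, gene, category, distance.
    """
    rows = []
    for marker in sorted(marker_coords):
        contig, pos = marker_coords[marker]
        genes = annotation.contig_genes(contig)
        if not genes:
            logger.warning("marker %s on unknown contig %s", marker, contig)
            rows.append((marker, None, "unassigned", np.nan))
            continue
        inside = [g for g in genes if g.start <= pos <= g.end]
        if len(inside) > 1:
            rows.append((marker, None, "ambiguous", 0.0))
            continue
        if len(inside) == 1:
            g = inside[0]
            in_exon = any(s <= pos <= e for s, e in g.exons)
            rows.append((marker, g.gene_id, "exon" if in_exon else "intron", 0.0))
            continue
        dists = np.array(
            [g.start - pos if pos < g.start else pos - g.end for g in genes]
        )
        dmin = dists.min()
        if dmin > window:
            rows.append((marker, None, "unassigned", float(dmin)))
            continue
        nearest = np.flatnonzero(dists == dmin)
        if len(nearest) > 1:
            rows.append((marker, None, "ambiguous", float(dmin)))
            continue
        g = genes[int(nearest[0])]
        rows.append((marker, g.gene_id, "intergenic_linked", float(dmin)))
    return pd.DataFrame(rows, columns=["marker", "gene", "category", "distance"])


def load_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> gene-to-terms mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def fisher_enrichment(
    study_genes: set[str],
    term_map: dict[str, set[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each term in the study set.

    The universe defaults to all genes with at least one term.  A term is
    flagged enriched when its BH q-value is below ``alpha`` AND it is
    represented by at least ``min_genes`` study genes.
    """
    if universe is None:
        universe = set(term_map)
    study = set(study_genes) & universe
    if not set(study_genes) <= universe:
        logger.warning(
            "%d study genes outside the universe were ignored",
            len(set(study_genes) - universe),
        )
    cols = ["term", "k", "n", "K_t", "N", "p", "q", "enriched"]
    if not study:
        logger.warning("empty study set; no enrichment computed")
        return pd.DataFrame(columns=cols)

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N, n = len(universe), len(study)
    rows = []
    for term in sorted(term_genes):
        K_t = len(term_genes[term])
        k = len(term_genes[term] & study)
        p = float(stats.hypergeom.sf(k - 1, N, K_t, n))
        rows.append((term, k, n, K_t, N, p))
    df = pd.DataFrame(rows, columns=cols[:6])
    _, q, _, _ = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["enriched"] = (df["q"] < alpha) & (df["k"] >= min_genes)
    return df.sort_values("p", kind="stable").reset_index(drop=True)
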