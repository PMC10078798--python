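"""Linking enhancers, variants, and validated elements to genes.

Implements the basal-plus-extension regulatory-domain rule (5 kb upstream /
1 kb downstream of the TSS, extended toward the nearest neighbouring gene's
basal domain up to 1 Mb), fixed-window proximity queries (500 kbp for GWAS
variants, 1 Mb for validated in vivo enhancers), and the retention filters
applied to GWAS and differential-expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .genomic_core import GeneRecord, GenomicInterval, VariantRecord
from .enhancer_extraction import EnhancerSet

__all__ = [
    "RegulatoryDomain",
    "LinkTable",
    "build_regulatory_domains",
    "assign_enhancers_to_genes",
    "genes_near_variants",
    "genes_near_intervals",
    "filter_gwas_variants",
    "filter_de_genes",
    "GREAT_BASAL_UP",
    "GREAT_BASAL_DOWN",
    "GREAT_MAX_EXTENSION",
]

# Basal-plus-extension defaults (the association rule's documented defaults).
GREAT_BASAL_UP = 5_000
GREAT_BASAL_DOWN = 1_000
GREAT_MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class RegulatoryDomain:
    """A gene's basal and extended regulatory span.

    ``basal`` is the strand-oriented fixed window around the TSS; ``extended``
    grows each side until the nearest other gene's basal edge or the
    extension cap, whichever is closer, clipped to the chromosome.
    """

    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval
    tss: int

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValueError(f"{self.gene_id}: basal domain not inside extended")


def _basal_span(gene: GeneRecord, basal_up: int, basal_down: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - basal_up, gene.tss + basal_down
    return gene.tss - basal_down, gene.tss + basal_up


def build_regulatory_domains(
    genes: list[GeneRecord],
    chrom_sizes: dict[str, int],
    basal_up: int = GREAT_BASAL_UP,
    basal_down: int = GREAT_BASAL_DOWN,
    max_extension: int = GREAT_MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for every gene.

    Extension on each side stops at the nearest other gene's basal-domain
    edge when that is closer than ``max_extension``; genes with identical TSS
    do not truncate each other. Domains may overlap. Order of the input gene
    list is preserved.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} not in chrom_sizes")

    raw_basal: dict[str, tuple[int, int]] = {
        g.gene_id: _basal_span(g, basal_up, basal_down) for g in genes
    }
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: list[RegulatoryDomain] = []
    for g in genes:
        size = chrom_sizes[g.chrom]
        bs, be = raw_basal[g.gene_id]
        bs_c, be_c = max(0, bs), min(size, be)

        left_edges = [
            raw_basal[o.gene_id][1]
            for o in by_chrom[g.chrom]
            if o.gene_id != g.gene_id and o.tss < g.tss
        ]
        right_edges = [
            raw_basal[o.gene_id][0]
            for o in by_chrom[g.chrom]
            if o.gene_id != g.gene_id and o.tss > g.tss
        ]
        ext_s = bs - max_extension
        if left_edges:
            ext_s = max(ext_s, max(left_edges))
        ext_e = be + max_extension
        if right_edges:
            ext_e = min(ext_e, min(right_edges))
        # extension never shrinks below the basal domain, and stays on-chrom
        ext_s = max(0, min(ext_s, bs_c))
        ext_e = min(size, max(ext_e, be_c))
        domains.append(
            RegulatoryDomain(
                gene_id=g.gene_id,
                basal=GenomicInterval(g.chrom, bs_c, be_c),
                extended=GenomicInterval(g.chrom, ext_s, ext_e),
                tss=g.tss,
            )
        )
    return domains


@dataclass
class LinkTable:
    """Enhancer-to-gene assignments with per-link signed midpoint-TSS distances."""

    links: pd.DataFrame  # gene_id, chrom, start, end, distance

    def counts(self) -> dict[str, int]:
        if self.links.empty:
            return {}
        return self.links.groupby("gene_id").size().to_dict()

    def n_links(self) -> int:
        return len(self.links)


def assign_enhancers_to_genes(
    enhancers: EnhancerSet, domains: list[RegulatoryDomain]
) -> LinkTable:
    """Assign each enhancer to every gene whose extended domain it overlaps
    by >= 1 bp (multi-assignment allowed)."""
    trees: dict[str, IntervalTree] = {}
    for dom in domains:
        trees.setdefault(dom.extended.chrom, IntervalTree()).addi(
            dom.extended.start, dom.extended.end, dom
        )
    rows = []
    for iv in enhancers.intervals:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end), key=lambda h: h.data.gene_id):
            dom = hit.data
            rows.append(
                {
                    "gene_id": dom.gene_id,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "distance": iv.midpoint - dom.tss,
                }
            )
    return LinkTable(
        links=pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "distance"])
    )


def _point_to_span_bp(pos: int, start: int, end: int) -> int:
    """Base distance from a 0-based position to the nearest base of [start, end)."""
    return max(start - pos, pos - (end - 1), 0)


def genes_near_variants(
    genes: list[GeneRecord],
    variants: list[VariantRecord],
    window: int = 500_000,
    anchor: str = "span",
) -> set[str]:
    """Genes whose span (or TSS) lies within ``window`` bp of >= 1 variant.

    Distance is measured to the nearest base of the gene body when
    ``anchor="span"`` (0 for a variant inside the gene) or to the TSS base
    when ``anchor="tss"``; the boundary is inclusive and only same-chromosome
    variants count.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if anchor not in ("span", "tss"):
        raise ValueError(f"unknown anchor {anchor!r}")
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    hits: set[str] = set()
    for g in genes:
        for pos in by_chrom.get(g.chrom, ()):
            if anchor == "span":
                d = _point_to_span_bp(pos, g.start, g.end)
            else:
                d = abs(pos - g.tss)
            if d <= window:
                hits.add(g.gene_id)
                break
    return hits


def genes_near_intervals(
    genes: list[GeneRecord],
    elements: list[GenomicInterval],
    window: int = 1_000_000,
) -> set[str]:
    """Genes whose span lies within ``window`` bp (half-open gap, boundary
    inclusive) of >= 1 element on the same chromosome."""
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    hits: set[str] = set()
    for g in genes:
        for el in by_chrom.get(g.chrom, ()):
            gap = max(g.start - el.end, el.start - g.end, 0)
            if gap <= window:
                hits.add(g.gene_id)
                break
    return hits


def filter_gwas_variants(
    variants: list[VariantRecord],
    alpha: float = 5e-8,
    traits: set[str] | None = None,
) -> list[VariantRecord]:
    """Keep genome-wide-significant variants (p <= alpha, boundary inclusive)
    matching the trait set (all traits when the set is empty or None);
    identical (variant_id, chrom, pos) rows are deduplicated, first wins.
    Multi-mapping rsIDs (same id, different positions) are all kept."""
    seen: set[tuple[str, str, int]] = set()
    out = []
    for v in variants:
        if v.pvalue > alpha:
            continue
        if traits and v.trait not in traits:
            continue
        key = (v.variant_id, v.chrom, v.pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


def filter_de_genes(
    de_table: pd.DataFrame,
    lfc_min: float = 2.0,
    padj_max: float = 0.05,
) -> set[str]:
    """Differential-expression retention filter: log2 fold change strictly
    greater than ``lfc_min`` and adjusted p at most ``padj_max``.

    The table needs columns gene_id, log2fc, padj.
    """
    required = ["gene_id", "log2fc", "padj"]
    missing = [c for c in required if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    bad = de_table["padj"].astype(float)
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("DE table padj outside [0, 1]")
    keep = (de_table["log2fc"].astype(float) > lfc_min) & (bad <= padj_max)
    return set(de_table.loc[keep, "gene_id"].astype(str))
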