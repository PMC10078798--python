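"""Composite evidence scoring and ranking of candidate odontogenic loci.

Each gene accumulates points across eight evidence components:

==========================  ======  =======================================
component                   points  awarded for
==========================  ======  =======================================
marker                      0/1     marker gene of any annotated cell type
dental marker               0/1     marker of a dental cell type (enamel
                                    knot, epithelium, mesenchyme,
                                    perivascular cells)
GWAS proximity              0/1     within 500 kbp of an associated variant
TSE bucket                  0-4     predicted targeting tissue-specific
                                    enhancers: 0 -> 0, 1-2 -> 1, 3-4 -> 2,
                                    5-6 -> 3, 7+ -> 4
module enrichment           0-3     co-expression module enriched for
                                    enhancer targets / dental-phenotype
                                    ontology genes / DEGs (one point each)
VISTA proximity             0/1     within 1 Mb of a validated enhancer
tooth-enhancer target       0/1     targeted by >= 1 tooth enhancer
DEG                         0/1     tooth-biased differential expression
==========================  ======  =======================================

The maximum total is 13. Genes in the grey (unassigned) co-expression
module are excluded before ranking; ties on the total score break on the
predicted TSE count, then lexicographic gene id for full determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .enrichment_stats import ModuleFlags

__all__ = [
    "DENTAL_CELL_TYPES",
    "GeneEvidence",
    "ScoreBreakdown",
    "tse_bucket_points",
    "dental_marker_points",
    "module_points",
    "score_gene",
    "rank_genes",
]

#: Dental-specific single-cell cluster annotations.
DENTAL_CELL_TYPES = frozenset(
    {"Enamel Knot", "Epithelium", "Mesenchyme", "Perivascular Cells"}
)


@dataclass
class GeneEvidence:
    """Consolidated per-gene evidence feeding the score."""

    gene_id: str
    module: str = ""
    is_marker: bool = False
    marker_cell_types: frozenset[str] = field(default_factory=frozenset)
    near_gwas_variant: bool = False
    n_tse: int = 0
    n_ste: int = 0
    module_flags: ModuleFlags = field(default_factory=ModuleFlags)
    near_vista: bool = False
    is_te_target: bool = False
    is_deg: bool = False

    def __post_init__(self) -> None:
        self.marker_cell_types = frozenset(self.marker_cell_types)
        if self.marker_cell_types and not self.is_marker:
            raise ValueError(
                f"{self.gene_id}: marker cell types given but is_marker is False"
            )
        if self.n_tse < 0 or self.n_ste < 0:
            raise ValueError(f"{self.gene_id}: enhancer counts must be >= 0")


@dataclass
class ScoreBreakdown:
    """Per-gene component points, total, and tie-break key."""

    gene_id: str
    pts_marker: int
    pts_dental_marker: int
    pts_gwas: int
    pts_tse_bucket: int
    pts_module: int
    pts_vista: int
    pts_te_target: int
    pts_deg: int
    total: int
    tiebreak: int

    def components(self) -> dict[str, int]:
        return {
            "pts_marker": self.pts_marker,
            "pts_dental_marker": self.pts_dental_marker,
            "pts_gwas": self.pts_gwas,
            "pts_tse_bucket": self.pts_tse_bucket,
            "pts_module": self.pts_module,
            "pts_vista": self.pts_vista,
            "pts_te_target": self.pts_te_target,
            "pts_deg": self.pts_deg,
        }


def tse_bucket_points(n_tse: int) -> int:
    """Piecewise bucket for the predicted targeting-TSE count."""
    if n_tse < 0:
        raise ValueError("TSE count must be >= 0")
    if n_tse == 0:
        return 0
    if n_tse <= 2:
        return 1
    if n_tse <= 4:
        return 2
    if n_tse <= 6:
        return 3
    return 4


def dental_marker_points(
    cell_types: frozenset[str] | set[str],
    dental_types: frozenset[str] = DENTAL_CELL_TYPES,
) -> int:
    """1 iff any marker cell type is dental-specific."""
    return 1 if set(cell_types) & set(dental_types) else 0


def module_points(flags: ModuleFlags, scoring: str = "per-category") -> int:
    """Points for co-expression module enrichment: one per enriched category
    (default) or a 0/1 lump sum."""
    if scoring == "per-category":
        return flags.n_true()
    if scoring == "lump":
        return 1 if flags.n_true() > 0 else 0
    raise ValueError(f"unknown module scoring {scoring!r}")


def score_gene(
    ev: GeneEvidence,
    module_scoring: str = "per-category",
    tiebreak: str = "tse",
) -> ScoreBreakdown:
    """Score one gene's evidence; a pure function of the evidence record."""
    if tiebreak not in ("tse", "ste"):
        raise ValueError(f"unknown tiebreak {tiebreak!r}")
    pts = {
        "pts_marker": 1 if ev.is_marker else 0,
        "pts_dental_marker": dental_marker_points(ev.marker_cell_types),
        "pts_gwas": 1 if ev.near_gwas_variant else 0,
        "pts_tse_bucket": tse_bucket_points(ev.n_tse),
        "pts_module": module_points(ev.module_flags, module_scoring),
        "pts_vista": 1 if ev.near_vista else 0,
        "pts_te_target": 1 if ev.is_te_target else 0,
        "pts_deg": 1 if ev.is_deg else 0,
    }
    return ScoreBreakdown(
        gene_id=ev.gene_id,
        total=sum(pts.values()),
        tiebreak=ev.n_tse if tiebreak == "tse" else ev.n_ste,
        **pts,
    )


def rank_genes(
    evidence: list[GeneEvidence],
    exclude_module: str | None = "grey",
    module_scoring: str = "per-category",
    tiebreak: str = "tse",
) -> list[ScoreBreakdown]:
    """Deterministic ranking: drop the excluded module, score, then sort by
    total desc, tie-break count desc, gene id asc. Rank is the 1-based list
    position."""
    ids = [ev.gene_id for ev in evidence]
    if len(ids) != len(set(ids)):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")
    retained = [
        ev for ev in evidence if exclude_module is None or ev.module != exclude_module
    ]
    scored = [score_gene(ev, module_scoring, tiebreak) for ev in retained]
    scored.sort(key=lambda sb: (-sb.total, -sb.tiebreak, sb.gene_id))
    return scored
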