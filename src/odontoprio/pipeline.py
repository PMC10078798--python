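"""End-to-end orchestration from a single flat config: extract strong
enhancers, subtract backgrounds, build regulatory domains, assign enhancers,
apply variant and VISTA proximity windows, retention filters, module
enrichment flags, evidence assembly, scoring, and deterministic ranking.

Re-running with an identical config and inputs is bit-identical on every
output (the run log carries the only timestamps, and only to stderr).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genomic_core as gc
from . import enhancer_extraction as ee
from . import gene_association as ga
from . import enrichment_stats as es
from . import prioritization as pr

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """Flat key-value run configuration (one provenance artifact per run)."""

    # inputs
    segmentation_target: str = ""
    segmentation_backgrounds: list[str] = field(default_factory=list)
    genes: str = ""
    chrom_sizes: str = ""
    variants: str = ""
    vista: str = ""
    markers: str = ""
    de: str = ""
    modules: str = ""
    ontology_genes: str = ""
    coordinate_map: str | None = None
    # parameters
    state_model: int = 18
    strong_states: list[int] = field(default_factory=lambda: [8, 9, 10])
    specificity_mode: str = "remove_whole"
    min_bp: int = 1
    basal_up: int = ga.GREAT_BASAL_UP
    basal_down: int = ga.GREAT_BASAL_DOWN
    max_extension: int = ga.GREAT_MAX_EXTENSION
    variant_window: int = 500_000
    variant_anchor: str = "span"
    vista_window: int = 1_000_000
    gwas_alpha: float = 5e-8
    gwas_traits: list[str] = field(default_factory=list)
    de_lfc_min: float = 2.0
    de_padj_max: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    tiebreak: str = "tse"
    module_scoring: str = "per-category"
    exclude_module: str = "grey"
    te_target_basis: str = "strong"  # or "specific"
    score_unmoduled: bool = False

    def __post_init__(self) -> None:
        if self.specificity_mode not in ("remove_whole", "trim"):
            raise ValueError(f"specificity_mode {self.specificity_mode!r} invalid")
        if self.te_target_basis not in ("strong", "specific"):
            raise ValueError(f"te_target_basis {self.te_target_basis!r} invalid")
        if self.variant_anchor not in ("span", "tss"):
            raise ValueError(f"variant_anchor {self.variant_anchor!r} invalid")
        if not (0 < self.gwas_alpha <= 1) or not (0 < self.alpha <= 1):
            raise ValueError("alpha parameters must lie in (0, 1]")
        if self.n_perm < 1 or self.min_bp < 1:
            raise ValueError("n_perm and min_bp must be >= 1")
        for name in ("variant_window", "vista_window", "basal_up", "basal_down",
                     "max_extension"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    _PATH_FIELDS = (
        "segmentation_target", "genes", "chrom_sizes", "variants", "vista",
        "markers", "de", "modules", "ontology_genes", "coordinate_map",
    )

    @classmethod
    def from_yaml(cls, path: str | Path, resolve_paths: bool = True) -> "PipelineConfig":
        """Load a flat YAML config; unknown keys are rejected. Relative input
        paths are resolved against the config file's directory."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if resolve_paths:
            base = Path(path).resolve().parent

            def _abs(p):
                return p if not p or Path(p).is_absolute() else str(base / p)

            for key in cls._PATH_FIELDS:
                if key in data and data[key]:
                    data[key] = _abs(data[key])
            if data.get("segmentation_backgrounds"):
                data["segmentation_backgrounds"] = [
                    _abs(p) for p in data["segmentation_backgrounds"]
                ]
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    ranked: pd.DataFrame
    evidence: dict[str, pr.GeneEvidence]
    breakdowns: list[pr.ScoreBreakdown]
    strong: ee.EnhancerSet
    specific: ee.EnhancerSet
    module_enrichment: es.ModuleEnrichment
    manifest: dict


def _require_files(config: PipelineConfig) -> None:
    paths = [
        config.segmentation_target, config.genes, config.chrom_sizes,
        config.variants, config.vista, config.markers, config.de,
        config.modules, config.ontology_genes,
        *config.segmentation_backgrounds,
    ]
    if config.coordinate_map:
        paths.append(config.coordinate_map)
    for p in paths:
        if not p:
            raise PipelineError("config: a required input path is empty")
        if not Path(p).exists():
            raise PipelineError(f"config: input file not found: {p}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write the ranked table, per-stage
    TSVs, the enrichment table, and a machine-readable run manifest."""
    _require_files(config)
    logger.info("run config hash %s, seed %d", config.content_hash()[:12], config.seed)

    # --- extract ----------------------------------------------------------
    @_stage("extract")
    def _extract():
        track = gc.read_segmentation(
            config.segmentation_target, state_model=config.state_model
        )
        strong = ee.extract_strong_enhancers(track, set(config.strong_states))
        bgs = []
        for p in config.segmentation_backgrounds:
            bt = gc.read_segmentation(p, state_model=config.state_model)
            bgs.append(ee.extract_strong_enhancers(bt, set(config.strong_states)))
        return strong, bgs

    strong, bg_strong = _extract()
    logger.info("strong enhancers: %d elements, %d bp", len(strong), strong.total_bp())

    # --- specific ---------------------------------------------------------
    @_stage("specific")
    def _specific():
        return ee.tissue_specific_enhancers(
            strong, bg_strong, mode=config.specificity_mode, min_bp=config.min_bp
        )

    specific = _specific()
    logger.info("tissue-specific enhancers: %d elements", len(specific))

    if config.coordinate_map:
        @_stage("coordinate_map")
        def _map():
            cmap = ee.read_coordinate_map(config.coordinate_map)
            mapped, rep = ee.apply_coordinate_map(specific, cmap)
            logger.info("coordinate map: %d/%d mapped", rep.n_mapped, rep.n_input)
            return mapped
        # mapped set kept as a side artifact; association stays in-assembly
        mapped_specific = _map()
    else:
        mapped_specific = None

    # --- associate --------------------------------------------------------
    @_stage("associate")
    def _associate():
        genes = gc.read_gene_table(config.genes)
        sizes = gc.read_chrom_sizes(config.chrom_sizes)
        domains = ga.build_regulatory_domains(
            genes, sizes,
            basal_up=config.basal_up, basal_down=config.basal_down,
            max_extension=config.max_extension,
        )
        links_strong = ga.assign_enhancers_to_genes(strong, domains)
        links_specific = ga.assign_enhancers_to_genes(specific, domains)
        return genes, domains, links_strong, links_specific

    genes, domains, links_strong, links_specific = _associate()
    n_ste = links_strong.counts()
    n_tse = links_specific.counts()

    # --- proximity --------------------------------------------------------
    @_stage("proximity")
    def _proximity():
        variants = gc.read_gwas_table(config.variants)
        kept = ga.filter_gwas_variants(
            variants, alpha=config.gwas_alpha,
            traits=set(config.gwas_traits) or None,
        )
        near_gwas = ga.genes_near_variants(
            genes, kept, window=config.variant_window, anchor=config.variant_anchor
        )
        vista = gc.read_bed(config.vista)
        near_vista = ga.genes_near_intervals(genes, vista, window=config.vista_window)
        return kept, near_gwas, near_vista

    kept_variants, near_gwas, near_vista = _proximity()
    logger.info("retained variants: %d; genes near variants: %d; near VISTA: %d",
                len(kept_variants), len(near_gwas), len(near_vista))

    # --- filters ----------------------------------------------------------
    @_stage("filters")
    def _filters():
        de = pd.read_csv(config.de, sep="\t")
        degs = ga.filter_de_genes(de, lfc_min=config.de_lfc_min,
                                  padj_max=config.de_padj_max)
        markers = pd.read_csv(config.markers, sep="\t")
        if not {"gene_id", "cell_type"} <= set(markers.columns):
            raise ValueError("marker table needs gene_id and cell_type columns")
        marker_types: dict[str, set[str]] = {}
        for r in markers.itertuples(index=False):
            marker_types.setdefault(str(r.gene_id), set()).add(str(r.cell_type))
        modules = pd.read_csv(config.modules, sep="\t")
        if not {"gene_id", "module"} <= set(modules.columns):
            raise ValueError("module table needs gene_id and module columns")
        module_of = dict(zip(modules.gene_id.astype(str), modules.module.astype(str)))
        with open(config.ontology_genes) as fh:
            onto = {line.strip() for line in fh if line.strip()}
        return degs, marker_types, module_of, onto

    degs, marker_types, module_of, onto_genes = _filters()

    # --- module flags -----------------------------------------------------
    te_basis_counts = n_ste if config.te_target_basis == "strong" else n_tse
    te_targets = {g for g, n in te_basis_counts.items() if n > 0}

    @_stage("module_flags")
    def _flags():
        universe = set(module_of)
        members: dict[str, set[str]] = {}
        for gid, mod in module_of.items():
            members.setdefault(mod, set()).add(gid)
        return es.module_enrichment_flags(
            module_members=members,
            te_targets=te_targets,
            dental_ontology_genes=onto_genes,
            deg_set=degs,
            universe=universe,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha=config.alpha,
        )

    menr = _flags()

    # --- evidence assembly + score + rank ---------------------------------
    @_stage("score")
    def _score():
        evidence: dict[str, pr.GeneEvidence] = {}
        for g in genes:
            mod = module_of.get(g.gene_id)
            if mod is None and not config.score_unmoduled:
                continue
            mtypes = marker_types.get(g.gene_id, set())
            flags = menr.flags.get(mod, es.ModuleFlags()) if mod else es.ModuleFlags()
            evidence[g.gene_id] = pr.GeneEvidence(
                gene_id=g.gene_id,
                module=mod or "",
                is_marker=bool(mtypes),
                marker_cell_types=frozenset(mtypes),
                near_gwas_variant=g.gene_id in near_gwas,
                n_tse=n_tse.get(g.gene_id, 0),
                n_ste=n_ste.get(g.gene_id, 0),
                module_flags=flags,
                near_vista=g.gene_id in near_vista,
                is_te_target=g.gene_id in te_targets,
                is_deg=g.gene_id in degs,
            )
        ranked = pr.rank_genes(
            list(evidence.values()),
            exclude_module=config.exclude_module or None,
            module_scoring=config.module_scoring,
            tiebreak=config.tiebreak,
        )
        return evidence, ranked

    evidence, breakdowns = _score()

    rows = []
    for rank, sb in enumerate(breakdowns, start=1):
        ev = evidence[sb.gene_id]
        rows.append(
            {
                "rank": rank,
                "gene_id": sb.gene_id,
                "total": sb.total,
                "module": ev.module,
                "deg": "Yes" if ev.is_deg else "No",
                "marker_cell_types": ";".join(sorted(ev.marker_cell_types)) or "No",
                "n_tse": ev.n_tse,
                "n_ste": ev.n_ste,
                **sb.components(),
            }
        )
    ranked_df = pd.DataFrame(rows)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_strong": len(strong),
        "n_specific": len(specific),
        "n_retained_variants": len(kept_variants),
        "n_degs": len(degs),
        "n_ranked": len(ranked_df),
        "inputs": {
            p: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in [config.segmentation_target, *config.segmentation_backgrounds,
                      config.genes, config.variants, config.vista, config.markers,
                      config.de, config.modules, config.ontology_genes]
        },
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gc.write_bed(
            [dataclasses.replace(iv, label=f"{strong.sample_id}:strong")
             for iv in strong.intervals],
            out / "strong_enhancers.bed",
        )
        gc.write_bed(
            [dataclasses.replace(iv, label=f"{specific.sample_id}:tissue_specific")
             for iv in specific.intervals],
            out / "tissue_specific_enhancers.bed",
        )
        if mapped_specific is not None:
            gc.write_bed(mapped_specific.intervals, out / "mapped_specific_enhancers.bed")
        links_strong.links.to_csv(out / "links_strong.tsv", sep="\t", index=False)
        links_specific.links.to_csv(out / "links_specific.tsv", sep="\t", index=False)
        menr.table.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
        ranked_df.to_csv(out / "ranked.tsv", sep="\t", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        ranked=ranked_df,
        evidence=evidence,
        breakdowns=breakdowns,
        strong=strong,
        specific=specific,
        module_enrichment=menr,
        manifest=manifest,
    )
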