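"""Seeded generator of a toy multi-tissue genomic world with planted structure.

The world emulates the statistical shape of the real study's inputs at desk
scale: multi-tissue 18-state chromatin segmentations with planted
strong-enhancer states (8-10), a target "tooth" tissue whose unique strong
elements are the planted tissue-specific enhancers, gene models whose basal
regulatory domains hold those elements (so enhancer-to-gene truth is exact
by construction), GWAS-style variants at controlled distances including the
proximity-window boundary, VISTA-style validated elements, and marker /
differential-expression / co-expression-module tables with planted
cell-type, DEG, and module-enrichment structure.

Gene classes cycle high / mid / null:

* high — 7-10 tissue-specific enhancers, dental marker, DEG, dental-ontology
  member, module "red" (enriched for enhancer targets, ontology genes, and
  DEGs by complete containment);
* mid — 1-4 tissue-specific enhancers, non-dental marker, module "blue"
  (enriched for enhancer targets only);
* null — no evidence, module "green" or (every third) the excluded "grey".

Two extra genes on an isolated chromosome pin the variant-window boundary:
one variant exactly at the window, one at window + 1. Ground truth
(evidence, score components, ranking) is computed by construction from the
planted coordinates with plain arithmetic, before any pipeline code runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import GeneRecord, GenomicInterval, SegmentationTrack, write_bed

__all__ = ["PlantSpec", "SyntheticWorld", "generate_world", "write_world"]

_DENTAL_TYPES = ["Enamel Knot", "Epithelium", "Mesenchyme", "Perivascular Cells"]
_NON_DENTAL_TYPES = ["Bone Progenitor Cells", "Endothelial Cells", "Erythrocytes"]


@dataclass
class PlantSpec:
    """Knobs of the planted world; defaults are the study conditions."""

    chrom_size: int = 10_000_000
    boundary_chrom_size: int = 4_000_000
    gene_pitch: int = 300_000
    first_gene_pos: int = 800_000
    gene_length: int = 10_000
    high_tse_range: tuple[int, int] = (7, 10)  # inclusive
    mid_tse_range: tuple[int, int] = (1, 4)
    high_shared: int = 2  # strong in target AND backgrounds -> not TSE
    mid_shared: int = 1
    enhancer_length: int = 120
    enhancer_pitch: int = 250
    variant_window: int = 500_000
    vista_window: int = 1_000_000
    gwas_alpha: float = 5e-8
    gwas_traits: tuple[str, ...] = ("odontogenesis", "tooth eruption")
    de_lfc_min: float = 2.0
    de_padj_max: float = 0.05
    basal_up: int = 5_000
    basal_down: int = 1_000


# module-enrichment truth by design (containment -> True, zero overlap -> False)
_MODULE_FLAG_TRUTH = {
    "red": (True, True, True),
    "blue": (True, False, False),
    "green": (False, False, False),
    "grey": (False, False, False),
}


@dataclass
class SyntheticWorld:
    seed: int
    spec: PlantSpec
    chrom_sizes: dict[str, int]
    genes: list[GeneRecord]
    tracks: dict[str, SegmentationTrack]
    target_sample: str
    variants_table: pd.DataFrame  # on-disk GWAS dialect (1-based positions)
    vista_elements: list[GenomicInterval]
    marker_table: pd.DataFrame
    de_table: pd.DataFrame
    module_table: pd.DataFrame
    ontology_genes: set[str]
    truth: dict = field(default_factory=dict)


def _tse_points(n: int) -> int:
    # generator-side copy of the published bucket, kept independent of the
    # scoring module so truth never flows through pipeline code
    if n == 0:
        return 0
    if n in (1, 2):
        return 1
    if n in (3, 4):
        return 2
    if n in (5, 6):
        return 3
    return 4


def generate_world(
    seed: int,
    n_genes: int = 60,
    n_tissues: int = 4,
    plant_spec: PlantSpec | None = None,
) -> SyntheticWorld:
    """Build a fully planted world; identical seed -> identical world."""
    sp = plant_spec or PlantSpec()
    if n_genes < 2 or n_genes % 2:
        raise ValueError("n_genes must be an even integer >= 2")
    if n_tissues < 2:
        raise ValueError("need a target plus at least one background tissue")
    per_chrom = n_genes // 2
    last_end = sp.first_gene_pos + (per_chrom - 1) * sp.gene_pitch + sp.gene_length
    if last_end + sp.basal_up > sp.chrom_size:
        raise ValueError("infeasible plant: genes overflow the chromosome")
    n_slots_needed = max(sp.high_tse_range[1] + sp.high_shared, sp.mid_tse_range[1] + sp.mid_shared)
    usable = sp.basal_up + sp.basal_down - 200
    if n_slots_needed * sp.enhancer_pitch > usable:
        raise ValueError("infeasible plant: more enhancers than basal-domain space")

    rng = np.random.default_rng(seed)
    chrom_sizes = {
        "chr1": sp.chrom_size,
        "chr2": sp.chrom_size,
        "chr3": sp.boundary_chrom_size,
    }

    # ---- genes -----------------------------------------------------------
    genes: list[GeneRecord] = []
    klass: dict[str, str] = {}
    for i in range(n_genes):
        chrom = "chr1" if i < per_chrom else "chr2"
        j = i if i < per_chrom else i - per_chrom
        start = sp.first_gene_pos + j * sp.gene_pitch
        gid = f"g{i:03d}"
        genes.append(
            GeneRecord(
                gene_id=gid,
                symbol=f"Gene{i:03d}",
                chrom=chrom,
                start=start,
                end=start + sp.gene_length,
                strand="+" if i % 2 == 0 else "-",
                ortholog_id=f"HG{i:03d}",
            )
        )
        klass[gid] = ("high", "mid", "null")[i % 3]
    # isolated boundary genes pinning the variant window
    for gid, start in (("gx_in", 1_000_000), ("gx_out", 2_900_000)):
        genes.append(
            GeneRecord(
                gene_id=gid, symbol=gid.upper(), chrom="chr3",
                start=start, end=start + sp.gene_length, strand="+",
                ortholog_id=None,
            )
        )
        klass[gid] = "boundary"

    gene_by_id = {g.gene_id: g for g in genes}

    # ---- modules ---------------------------------------------------------
    module_of: dict[str, str] = {}
    null_seen = 0
    for g in genes:
        k = klass[g.gene_id]
        if k == "high":
            module_of[g.gene_id] = "red"
        elif k == "mid":
            module_of[g.gene_id] = "blue"
        elif k == "boundary":
            module_of[g.gene_id] = "green"
        else:
            module_of[g.gene_id] = "grey" if null_seen % 3 == 2 else "green"
            null_seen += 1

    # ---- enhancer plants -------------------------------------------------
    n_tse: dict[str, int] = {}
    n_shared: dict[str, int] = {}
    tse_ivs: list[GenomicInterval] = []
    strong_labels = ["8_EnhA1", "9_EnhA2", "10_EnhW1"]
    target_features: list[GenomicInterval] = []
    bg_features: list[list[GenomicInterval]] = [[] for _ in range(n_tissues - 1)]

    for g in genes:
        k = klass[g.gene_id]
        if k == "high":
            nt = int(rng.integers(sp.high_tse_range[0], sp.high_tse_range[1] + 1))
            ns = sp.high_shared
        elif k == "mid":
            nt = int(rng.integers(sp.mid_tse_range[0], sp.mid_tse_range[1] + 1))
            ns = sp.mid_shared
        else:
            nt = ns = 0
        n_tse[g.gene_id], n_shared[g.gene_id] = nt, ns
        if nt + ns == 0:
            continue
        if g.strand == "+":
            slot0 = g.tss - sp.basal_up + 100
        else:
            slot0 = g.tss - sp.basal_down + 100
        for s in range(nt + ns):
            a = slot0 + s * sp.enhancer_pitch
            iv = GenomicInterval(g.chrom, a, a + sp.enhancer_length,
                                 strong_labels[s % 3])
            target_features.append(iv)
            if s < nt:
                tse_ivs.append(GenomicInterval(g.chrom, a, a + sp.enhancer_length))
            else:
                bg_i = s % (n_tissues - 1)
                if s % 2 == 1:  # background covers only the tail half: still disqualifies
                    half = a + sp.enhancer_length // 2
                    bg_features[bg_i].append(
                        GenomicInterval(g.chrom, half, a + sp.enhancer_length, "8_EnhA1")
                    )
                else:
                    bg_features[bg_i].append(
                        GenomicInterval(g.chrom, a, a + sp.enhancer_length, "9_EnhA2")
                    )
        # non-strong distractor upstream of the basal domain
        d0 = g.start - 20_000
        if d0 > 0:
            target_features.append(GenomicInterval(g.chrom, d0, d0 + 400, "4_TxWk"))

    # background-exclusive strong enhancers in intergenic space
    for i, g in enumerate(genes):
        if g.chrom == "chr3" or i % 4 != 0:
            continue
        a = g.start + 150_000
        bg_features[i % (n_tissues - 1)].append(
            GenomicInterval(g.chrom, a, a + 500, "8_EnhA1")
        )

    def _fill_track(sample_id: str, features: list[GenomicInterval]) -> SegmentationTrack:
        segs: list[GenomicInterval] = []
        by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
        for iv in features:
            by_chrom[iv.chrom].append(iv)
        for chrom in sorted(chrom_sizes):
            pos = 0
            for iv in sorted(by_chrom[chrom], key=lambda v: v.start):
                if iv.start > pos:
                    segs.append(GenomicInterval(chrom, pos, iv.start, "1_TssA"))
                segs.append(iv)
                pos = iv.end
            if pos < chrom_sizes[chrom]:
                segs.append(GenomicInterval(chrom, pos, chrom_sizes[chrom], "1_TssA"))
        return SegmentationTrack(sample_id=sample_id, segments=segs, state_model=18)

    tracks = {"tooth": _fill_track("tooth", target_features)}
    for b in range(n_tissues - 1):
        sid = f"background_{b + 1}"
        tracks[sid] = _fill_track(sid, bg_features[b])

    # ---- GWAS variants ---------------------------------------------------
    var_rows: list[dict] = []

    def _add_variant(vid: str, chrom: str, pos0: int, p: float, trait: str) -> None:
        var_rows.append(
            {"SNPS": vid, "CHR_ID": chrom, "CHR_POS": pos0 + 1,
             "P-VALUE": f"{p:.3e}", "MAPPED_TRAIT": trait}
        )

    vnum = 0
    for i, g in enumerate(genes):
        k = klass[g.gene_id]
        if k == "high" and (i // 3) % 2 == 0:
            p = 10 ** -float(rng.uniform(8.5, 20))
            _add_variant(f"rs{1000 + vnum}", g.chrom, g.start + 5_000, p, "odontogenesis")
            vnum += 1
        elif k == "null" and (i // 3) % 2 == 0:
            _add_variant(f"rs{1000 + vnum}", g.chrom, g.start + 5_000, 1e-5, "odontogenesis")
            vnum += 1
        elif k == "mid" and (i // 3) % 4 == 1:
            _add_variant(f"rs{1000 + vnum}", g.chrom, g.start + 5_000, 1e-12, "body height")
            vnum += 1
    gin, gout = gene_by_id["gx_in"], gene_by_id["gx_out"]
    _add_variant("rs_bnd_in", "chr3", gin.end - 1 + sp.variant_window, 1e-10, "odontogenesis")
    _add_variant("rs_bnd_out", "chr3", gout.start - sp.variant_window - 1, 1e-10, "tooth eruption")
    if var_rows:
        var_rows.append(dict(var_rows[0]))  # exact duplicate row (dedup exercise)
        multi = dict(var_rows[0])
        multi["CHR_POS"] = int(multi["CHR_POS"]) + 40_000  # multi-mapping rsID, kept
        var_rows.append(multi)
    variants_table = pd.DataFrame(var_rows)

    # ---- VISTA elements --------------------------------------------------
    vista: list[GenomicInterval] = []
    vn = 0
    for i, g in enumerate(genes):
        if klass[g.gene_id] == "high" and (i // 3) % 2 == 1:
            a = g.start - 150_000
            vista.append(GenomicInterval(g.chrom, a, a + 1_000, f"hs{9000 + vn}"))
            vn += 1
    vista.append(GenomicInterval("chr3", 3_950_000, 3_951_000, "hs_decoy"))

    # ---- marker / DE / module tables ------------------------------------
    marker_rows = []
    marker_types: dict[str, set[str]] = {}
    for i, g in enumerate(genes):
        k = klass[g.gene_id]
        types: set[str] = set()
        if k == "high":
            types.add(_DENTAL_TYPES[(i // 3) % 4])
            if (i // 3) % 3 == 0:
                types.add(_NON_DENTAL_TYPES[0])
        elif k == "mid":
            types.add(_NON_DENTAL_TYPES[(i // 3) % 3])
        for t in sorted(types):
            marker_rows.append(
                {"gene_id": g.gene_id, "cell_type": t,
                 "avg_log2FC": round(float(rng.uniform(1.0, 3.0)), 4),
                 "p_val_adj": float(f"{10 ** -float(rng.uniform(5, 50)):.3e}")}
            )
        marker_types[g.gene_id] = types
    marker_table = pd.DataFrame(marker_rows)

    de_rows = []
    mid_ids = [g.gene_id for g in genes if klass[g.gene_id] == "mid"]
    bd_lfc, bd_padj = mid_ids[0], mid_ids[1]  # DE-filter boundary plants
    for g in genes:
        k = klass[g.gene_id]
        if k == "high":
            lfc = round(float(rng.uniform(2.5, 6.0)), 4)
            padj = float(f"{10 ** -float(rng.uniform(4, 12)):.3e}")
        elif g.gene_id == bd_lfc:
            lfc, padj = 2.0, 0.01  # exactly at the strict > threshold: not a DEG
        elif g.gene_id == bd_padj:
            lfc, padj = 2.5, 0.05  # inclusive <= boundary: a DEG
        else:
            lfc = round(float(rng.uniform(-1.5, 1.8)), 4)
            padj = round(float(rng.uniform(0.0, 1.0)), 6)
        de_rows.append({"gene_id": g.gene_id, "log2fc": lfc, "padj": padj})
    de_table = pd.DataFrame(de_rows)

    module_table = pd.DataFrame(
        [{"gene_id": g.gene_id, "module": module_of[g.gene_id]} for g in genes]
    )
    ontology_genes = {g.gene_id for g in genes if klass[g.gene_id] == "high"}

    # ---- ground truth, by construction -----------------------------------
    deg_truth = {
        r["gene_id"] for r in de_rows
        if r["log2fc"] > sp.de_lfc_min and r["padj"] <= sp.de_padj_max
    }
    retained_pos: list[tuple[str, int]] = []
    seen_keys: set[tuple[str, str, int]] = set()
    for r in var_rows:
        p = float(r["P-VALUE"])
        if p > sp.gwas_alpha or r["MAPPED_TRAIT"] not in sp.gwas_traits:
            continue
        key = (r["SNPS"], r["CHR_ID"], int(r["CHR_POS"]) - 1)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        retained_pos.append((r["CHR_ID"], int(r["CHR_POS"]) - 1))

    truth_genes: dict[str, dict] = {}
    for g in genes:
        near_gwas = any(
            c == g.chrom and max(g.start - pos, pos - (g.end - 1), 0) <= sp.variant_window
            for c, pos in retained_pos
        )
        near_vista = any(
            v.chrom == g.chrom
            and max(g.start - v.end, v.start - g.end, 0) <= sp.vista_window
            for v in vista
        )
        nt, ns_ = n_tse[g.gene_id], n_shared[g.gene_id]
        mtypes = marker_types[g.gene_id]
        flags = _MODULE_FLAG_TRUTH[module_of[g.gene_id]]
        pts = {
            "pts_marker": 1 if mtypes else 0,
            "pts_dental_marker": 1 if mtypes & set(_DENTAL_TYPES) else 0,
            "pts_gwas": 1 if near_gwas else 0,
            "pts_tse_bucket": _tse_points(nt),
            "pts_module": sum(flags),
            "pts_vista": 1 if near_vista else 0,
            "pts_te_target": 1 if (nt + ns_) > 0 else 0,
            "pts_deg": 1 if g.gene_id in deg_truth else 0,
        }
        truth_genes[g.gene_id] = {
            "class": klass[g.gene_id],
            "module": module_of[g.gene_id],
            "evidence": {
                "is_marker": bool(mtypes),
                "marker_cell_types": sorted(mtypes),
                "near_gwas_variant": near_gwas,
                "n_tse": nt,
                "n_ste": nt + ns_,
                "module_flags": list(flags),
                "near_vista": near_vista,
                "is_te_target": (nt + ns_) > 0,
                "is_deg": g.gene_id in deg_truth,
            },
            "score": {**pts, "total": sum(pts.values()), "tiebreak": nt},
        }

    ranking = sorted(
        (gid for gid in truth_genes if module_of[gid] != "grey"),
        key=lambda gid: (
            -truth_genes[gid]["score"]["total"],
            -truth_genes[gid]["score"]["tiebreak"],
            gid,
        ),
    )
    truth = {
        "genes": truth_genes,
        "ranking": ranking,
        "tse_elements": [[iv.chrom, iv.start, iv.end] for iv in
                         sorted(tse_ivs, key=lambda v: (v.chrom, v.start))],
        "module_flags": {m: list(f) for m, f in _MODULE_FLAG_TRUTH.items()},
    }

    return SyntheticWorld(
        seed=seed,
        spec=sp,
        chrom_sizes=chrom_sizes,
        genes=genes,
        tracks=tracks,
        target_sample="tooth",
        variants_table=variants_table,
        vista_elements=vista,
        marker_table=marker_table,
        de_table=de_table,
        module_table=module_table,
        ontology_genes=ontology_genes,
        truth=truth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict:
    """Serialize every pipeline input in its on-disk format; returns the
    manifest (also written as manifest.json) listing files with checksums."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(world.chrom_sizes):
            fh.write(f"{chrom}\t{world.chrom_sizes[chrom]}\n")

    gene_df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
                "start": g.start, "end": g.end, "strand": g.strand,
                "ortholog_id": g.ortholog_id or "",
            }
            for g in world.genes
        ]
    )
    gene_df.to_csv(out / "genes.tsv", sep="\t", index=False)

    for sid, track in world.tracks.items():
        write_bed(track.segments, out / f"segmentation_{sid}.bed")

    world.variants_table.to_csv(out / "variants.tsv", sep="\t", index=False)
    write_bed(world.vista_elements, out / "vista.bed")
    world.marker_table.to_csv(out / "markers.tsv", sep="\t", index=False)
    world.de_table.to_csv(out / "de.tsv", sep="\t", index=False)
    world.module_table.to_csv(out / "modules.tsv", sep="\t", index=False)
    with open(out / "ontology_genes.txt", "w") as fh:
        for gid in sorted(world.ontology_genes):
            fh.write(gid + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(world.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    # ready-to-run flat config with paths relative to this directory
    from .pipeline import PipelineConfig

    cfg = PipelineConfig(
        segmentation_target="segmentation_tooth.bed",
        segmentation_backgrounds=sorted(
            f"segmentation_{sid}.bed" for sid in world.tracks if sid != world.target_sample
        ),
        genes="genes.tsv",
        chrom_sizes="chrom_sizes.tsv",
        variants="variants.tsv",
        vista="vista.bed",
        markers="markers.tsv",
        de="de.tsv",
        modules="modules.tsv",
        ontology_genes="ontology_genes.txt",
        gwas_alpha=world.spec.gwas_alpha,
        gwas_traits=list(world.spec.gwas_traits),
        de_lfc_min=world.spec.de_lfc_min,
        de_padj_max=world.spec.de_padj_max,
        variant_window=world.spec.variant_window,
        vista_window=world.spec.vista_window,
        basal_up=world.spec.basal_up,
        basal_down=world.spec.basal_down,
        seed=world.seed,
    )
    cfg.to_yaml(out / "config.yaml")

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": world.seed,
        "n_genes": len(world.genes),
        "files": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
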