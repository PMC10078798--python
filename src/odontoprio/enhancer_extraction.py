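"""Strong-enhancer extraction from chromatin-state segmentations and
tissue-specific enhancer derivation by multi-tissue subtraction.

Strong enhancers are the segments annotated with the strong-enhancer states
of the 18-state chromatin model (states 8-10 by default). Tissue-specific
enhancers are the strong enhancers of a target tissue absent from every
background tissue's strong set, either as whole discrete elements
(``remove_whole``, the default) or base-by-base (``trim``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genomic_core import (
    GenomicInterval,
    SegmentationTrack,
    merge_intervals,
    overlap_bp,
    state_number,
    subtract_intervals,
)

__all__ = [
    "EnhancerSet",
    "STRONG_ENHANCER_STATES",
    "extract_strong_enhancers",
    "tissue_specific_enhancers",
    "read_coordinate_map",
    "apply_coordinate_map",
    "MappingReport",
]

logger = logging.getLogger(__name__)

#: Strong-enhancer states of the 18-state chromatin model.
STRONG_ENHANCER_STATES = frozenset({8, 9, 10})


@dataclass
class EnhancerSet:
    """A merged, labeled enhancer interval collection for one sample."""

    sample_id: str
    kind: str  # "strong" | "tissue_specific"
    intervals: list[GenomicInterval]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("strong", "tissue_specific"):
            raise ValueError(f"unknown enhancer set kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def extract_strong_enhancers(
    track: SegmentationTrack,
    strong_states: frozenset[int] | set[int] = STRONG_ENHANCER_STATES,
) -> EnhancerSet:
    """Merged union of all segments whose state is in ``strong_states``.

    Adjacent strong segments (e.g. an 8 abutting a 9) coalesce into one
    enhancer element. An empty segmentation yields an empty set.
    """
    bad = {s for s in strong_states if not (1 <= s <= track.state_model)}
    if bad:
        raise ValueError(
            f"states {sorted(bad)} outside the {track.state_model}-state model"
        )
    picked = [
        seg
        for seg in track.segments
        if state_number(seg.label) in strong_states  # type: ignore[arg-type]
    ]
    return EnhancerSet(
        sample_id=track.sample_id,
        kind="strong",
        intervals=merge_intervals(picked),
        provenance=sorted({str(s) for s in strong_states}),
    )


def tissue_specific_enhancers(
    target: EnhancerSet,
    backgrounds: list[EnhancerSet],
    mode: str = "remove_whole",
    min_bp: int = 1,
) -> EnhancerSet:
    """Strong enhancers of ``target`` unique with respect to ``backgrounds``.

    ``remove_whole`` drops any target element sharing >= ``min_bp`` bases with
    any background element (an enhancer either is or is not unique);
    ``trim`` subtracts background bases, splitting elements as needed.
    """
    if target.kind != "strong":
        raise ValueError("target must be a strong enhancer set")
    if any(bg.kind != "strong" for bg in backgrounds):
        raise ValueError("backgrounds must be strong enhancer sets")
    if mode not in ("remove_whole", "trim"):
        raise ValueError(f"unknown specificity mode {mode!r}")

    bg_ivs = [iv for bg in backgrounds for iv in bg.intervals]
    if not bg_ivs:
        logger.warning(
            "no background enhancers supplied; the full strong set of %s "
            "is re-tagged tissue-specific",
            target.sample_id,
        )
        kept = list(target.intervals)
    elif mode == "remove_whole":
        bg_merged = merge_intervals(bg_ivs)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in bg_merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        kept = [
            iv
            for iv in target.intervals
            if not any(overlap_bp(iv, b) >= min_bp for b in by_chrom.get(iv.chrom, []))
        ]
    else:
        kept = subtract_intervals(target.intervals, bg_ivs)

    return EnhancerSet(
        sample_id=target.sample_id,
        kind="tissue_specific",
        intervals=kept,
        provenance=list(target.provenance),
    )


# ---------------------------------------------------------------------------
# cross-assembly coordinate maps
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end"]


@dataclass
class MappingReport:
    n_input: int
    n_mapped: int
    n_dropped: int


def read_coordinate_map(path: str) -> pd.DataFrame:
    """Read a precomputed 6-column cross-assembly map (TSV, headered).

    Rows must be non-overlapping on the source side; inverted coordinates on
    either side are a load error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing map columns {missing}")
    if ((df.src_start >= df.src_end) | (df.dst_start >= df.dst_end)).any():
        raise ValueError(f"{path}: map row with inverted coordinates")
    df = df.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)
    prev_end = df.groupby("src_chrom")["src_end"].shift()
    if ((df.src_start < prev_end).fillna(False)).any():
        raise ValueError(f"{path}: map rows overlap on the source side")
    return df


def apply_coordinate_map(
    es: EnhancerSet, cmap: pd.DataFrame
) -> tuple[EnhancerSet, MappingReport]:
    """Project an enhancer set through a precomputed coordinate map.

    Each interval overlapping a map row by >= 1 bp is projected: the
    overlapping portion is shifted by the row's source-to-destination offset
    and clipped to the destination span. Intervals overlapping several rows
    follow the row with the largest overlap (first wins on ties). Unmapped
    intervals are dropped and counted in the report.
    """
    rows = list(cmap.itertuples(index=False))
    projected: list[GenomicInterval] = []
    n_mapped = 0
    for iv in es.intervals:
        best = None
        best_ov = 0
        for r in rows:
            if r.src_chrom != iv.chrom:
                continue
            ov = min(iv.end, r.src_end) - max(iv.start, r.src_start)
            if ov > best_ov:
                best, best_ov = r, ov
        if best is None:
            continue
        n_mapped += 1
        seg_s = max(iv.start, best.src_start)
        seg_e = min(iv.end, best.src_end)
        offset = best.dst_start - best.src_start
        new_s = max(best.dst_start, seg_s + offset)
        new_e = min(best.dst_end, seg_e + offset)
        if new_s < new_e:
            projected.append(GenomicInterval(best.dst_chrom, new_s, new_e, iv.label))
    report = MappingReport(
        n_input=len(es.intervals), n_mapped=n_mapped, n_dropped=len(es.intervals) - n_mapped
    )
    return (
        EnhancerSet(
            sample_id=es.sample_id,
            kind=es.kind,
            intervals=merge_intervals(projected) if projected else [],
            provenance=list(es.provenance),
        ),
        report,
    )
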