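"""Coordinate conventions, interval algebra, and readers for BED-family and tabular inputs.

All coordinates are 0-based half-open (BED convention). Conversions from
1-based sources (GWAS catalog position columns) happen at load time only.
Chromosome names are matched by exact string comparison; no "chr" prefix
normalization is attempted, so mixed naming surfaces as a loud mismatch
rather than a silent rename. Strand is carried but ignored by all overlap
operations (enhancers are strandless).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "SegmentationTrack",
    "VariantRecord",
    "GeneRecord",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "overlap_bp",
    "overlaps_any",
    "read_segmentation",
    "read_gwas_table",
    "read_gene_table",
    "read_chrom_sizes",
    "state_number",
]

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED-family lines; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic span with 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_STATE_RE = re.compile(r"^(\d+)(?:_.*)?$")


def state_number(label: str) -> int:
    """Parse a chromatin-state label: bare integer or ``N_NAME`` — the leading
    integer is authoritative (ChromHMM dense-BED dialect)."""
    m = _STATE_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse chromatin state from label {label!r}")
    return int(m.group(1))


@dataclass
class SegmentationTrack:
    """One sample's chromatin-state segmentation (15- or 18-state model)."""

    sample_id: str
    segments: list[GenomicInterval]
    state_model: int = 18

    def __post_init__(self) -> None:
        if self.state_model not in (15, 18):
            raise ValueError("state_model must be 15 or 18")
        prev: GenomicInterval | None = None
        for seg in self.segments:
            if seg.label is None:
                raise ValueError("segmentation segment lacks a state label")
            st = state_number(seg.label)
            if not (1 <= st <= self.state_model):
                raise ValueError(
                    f"state {st} outside 1..{self.state_model} "
                    f"at {seg.chrom}:{seg.start}-{seg.end}"
                )
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"segments overlap or are unsorted at "
                    f"{seg.chrom}:{seg.start}-{seg.end}"
                )
            prev = seg

    def states(self) -> list[int]:
        return [state_number(s.label) for s in self.segments]  # type: ignore[arg-type]


@dataclass(frozen=True)
class VariantRecord:
    """A GWAS-catalog style association record; ``pos`` is 0-based."""

    variant_id: str
    chrom: str
    pos: int
    pvalue: float
    trait: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside (0, 1]")
        if self.pos < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True)
class GeneRecord:
    """A gene span with a strand-determined TSS (start base for +, end-1 for -)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    ortholog_id: str | None = None
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")
        object.__setattr__(
            self, "tss", self.start if self.strand == "+" else self.end - 1
        )


# ---------------------------------------------------------------------------
# interval algebra (bedtools semantics)
# ---------------------------------------------------------------------------


def _by_chrom(ivs: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in out.values():
        spans.sort()
    return out


def merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Maximal non-overlapping cover, per chromosome, sorted; touching
    intervals (end == next start) are merged and labels are dropped."""
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(ivs)):
        spans = _by_chrom(ivs)[chrom]
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-wise intersection of the merged covers of *a* and *b*."""
    am, bm = merge_intervals(a), merge_intervals(b)
    a_by, b_by = _by_chrom(am), _by_chrom(bm)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Every base covered by *a* and not by *b*, as maximal intervals.

    Intervals of *a* partially covered by *b* are trimmed or split, never
    dropped wholesale.
    """
    am = merge_intervals(a)
    b_by = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in am:
        cuts = b_by.get(iv.chrom, [])
        pos = iv.start
        for s, e in cuts:
            if e <= pos:
                continue
            if s >= iv.end:
                break
            if s > pos:
                out.append(GenomicInterval(iv.chrom, pos, min(s, iv.end)))
            pos = max(pos, e)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps_any(
    query: GenomicInterval,
    targets: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> bool:
    """True iff the query shares >= ``min_bp`` bases with any single target."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return any(overlap_bp(query, t) >= min_bp for t in targets)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4(+) into intervals; 4th column, when present, becomes the
    label. Order is preserved. Malformed lines raise :class:`BedParseError`
    naming the line number."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 fields")
            chrom, s_str, e_str = fields[0], fields[1], fields[2]
            try:
                start, end = int(s_str), int(e_str)
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            label = fields[3] if len(fields) > 3 and fields[3] != "" else None
            strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else None
            try:
                out.append(GenomicInterval(chrom, start, end, label, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_bed(ivs: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED3 (or BED4 when labels are present)."""
    with open(path, "w") as fh:
        for iv in ivs:
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_segmentation(
    path: str | Path, sample_id: str | None = None, state_model: int = 18
) -> SegmentationTrack:
    """Read a ChromHMM dense segmentation BED into a validated track."""
    ivs = read_bed(path)
    sid = sample_id if sample_id is not None else Path(path).stem
    ivs.sort(key=lambda iv: (iv.chrom, iv.start))
    return SegmentationTrack(sample_id=sid, segments=ivs, state_model=state_model)


#: GWAS-catalog default column names.
GWAS_COLUMNS = {
    "variant_id": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "pvalue": "P-VALUE",
    "trait": "MAPPED_TRAIT",
}


def read_gwas_table(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[VariantRecord]:
    """Read a GWAS-catalog style TSV. Positions are 1-based on disk and
    converted to the internal 0-based convention here.

    ``columns`` may remap the logical fields (variant_id, chrom, pos, pvalue,
    trait) onto the file's header names; defaults follow the catalog export.
    """
    cols = dict(GWAS_COLUMNS)
    if columns:
        unknown = set(columns) - set(cols)
        if unknown:
            raise ValueError(f"unknown GWAS column keys: {sorted(unknown)}")
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing GWAS columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            VariantRecord(
                variant_id=str(d[cols["variant_id"]]),
                chrom=str(d[cols["chrom"]]),
                pos=int(d[cols["pos"]]) - 1,
                pvalue=float(d[cols["pvalue"]]),
                trait=str(d[cols["trait"]]),
            )
        )
    return out


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene TSV (gene_id, symbol, chrom, start, end, strand[, ortholog_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene columns {missing}")
    has_ortho = "ortholog_id" in df.columns
    genes = []
    for d in df.to_dict("records"):
        ortho = d.get("ortholog_id") if has_ortho else None
        if isinstance(ortho, float) or ortho in ("", "nan", None):
            ortho = None
        genes.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                symbol=str(d["symbol"]),
                chrom=str(d["chrom"]),
                start=int(d["start"]),
                end=int(d["end"]),
                strand=str(d["strand"]),
                ortholog_id=ortho,
            )
        )
    return genes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, size) TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: need chrom<TAB>size")
            sizes[parts[0]] = int(parts[1])
    return sizes
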