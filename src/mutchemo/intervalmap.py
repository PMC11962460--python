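"""Sliding-window intersection mapping of independent induced alleles.

Given several independently mutagenised lines that share a phenotype, the
causal gene is expected to be the only place in the genome where *every*
line carries a (filtered) variant.  A fixed-width window slides along each
chromosome; windows in which all required lines have at least one variant
qualify, qualifying windows are merged into maximal candidate intervals,
and intervals are intersected with the gene annotation.  This is
intersection mapping of independent alleles, not recombination mapping, so
the per-line variants need not be at shared positions.

Internal coordinates are 1-based inclusive (VCF/GFF convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np

from .varfilter import Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with ordered CDS segments.

    ``cds_segments`` are 1-based inclusive (start, end) pairs sorted by
    genomic coordinate and non-overlapping, regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"{self.gene_id}: at least one CDS segment required")
        prev_end = 0
        for start, end in self.cds_segments:
            if start > end:
                raise ValueError(f"{self.gene_id}: segment {start}-{end} inverted")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or are unsorted")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]


@dataclass(frozen=True)
class WindowScanParams:
    """Sliding-window parameters; the 10-kb window is the published default."""

    window_size: int = 10_000
    step: int = 1_000
    min_lines: int | str = "all"

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window_size):
            raise ValueError("require 1 <= step <= window_size")
        if isinstance(self.min_lines, str) and self.min_lines != "all":
            raise ValueError("min_lines must be an integer or 'all'")
        if isinstance(self.min_lines, int) and self.min_lines < 1:
            raise ValueError("min_lines must be >= 1")


@dataclass(frozen=True)
class Window:
    """A qualifying window with the per-line variant positions inside it."""

    chrom: str
    start: int
    end: int
    per_line_positions: Mapping[str, tuple[int, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class GenomicInterval:
    """A merged candidate interval; positions listed per supporting line."""

    chrom: str
    start: int
    end: int
    per_line_variants: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end} inverted")
        for line, positions in self.per_line_variants.items():
            for p in positions:
                if not (self.start <= p <= self.end):
                    raise ValueError(
                        f"{line} variant at {p} outside {self.chrom}:{self.start}-{self.end}"
                    )

    @property
    def supporting_lines(self) -> int:
        return len(self.per_line_variants)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def window_scan(
    lines: Mapping[str, Sequence[Variant]],
    params: WindowScanParams = WindowScanParams(),
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Window]:
    """Enumerate windows in which every required line carries a variant.

    Windows start at offsets 1, 1+step, ... per chromosome; a window
    [s, s+window_size-1] qualifies iff at least ``min_lines`` lines (all of
    them by default) have >= 1 variant inside it.  Returns windows sorted by
    (chrom, start).
    """
    if not lines:
        raise ValueError("at least one line required")
    if chrom_lengths is None:
        chrom_lengths = {}
        for vs in lines.values():
            for v in vs:
                chrom_lengths[v.chrom] = max(chrom_lengths.get(v.chrom, 0), v.pos)
    else:
        for line_id, vs in lines.items():
            for v in vs:
                if v.chrom not in chrom_lengths:
                    raise ValueError(
                        f"{line_id}: variant chrom {v.chrom!r} missing from chrom_lengths"
                    )

    n_required = (
        len(lines) if params.min_lines == "all" else min(int(params.min_lines), len(lines))
    )
    empty = [lid for lid, vs in lines.items() if not vs]
    if empty and params.min_lines == "all":
        logger.info("lines with no variants under min_lines='all': %s", empty)
        return []

    w, step = params.window_size, params.step
    windows: list[Window] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_offsets = (length - 1) // step + 1
        counts = np.zeros(n_offsets, dtype=np.int32)
        per_line_pos: dict[str, np.ndarray] = {}
        for line_id, vs in lines.items():
            positions = np.array(sorted(v.pos for v in vs if v.chrom == chrom), dtype=np.int64)
            per_line_pos[line_id] = positions
            mask = np.zeros(n_offsets, dtype=bool)
            for pos in positions:
                k0 = max(0, math.ceil((pos - w) / step))
                k1 = min(n_offsets - 1, (pos - 1) // step)
                if k0 <= k1:
                    mask[k0 : k1 + 1] = True
            counts += mask
        for k in np.nonzero(counts >= n_required)[0]:
            start = 1 + int(k) * step
            end = start + w - 1
            per_line = {}
            for line_id, positions in per_line_pos.items():
                lo = np.searchsorted(positions, start, side="left")
                hi = np.searchsorted(positions, end, side="right")
                if hi > lo:
                    per_line[line_id] = tuple(int(p) for p in positions[lo:hi])
            windows.append(Window(chrom, start, end, per_line))
    return windows


def merge_windows(windows: Sequence[Window]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent qualifying windows into maximal intervals.

    Output intervals are disjoint, sorted, and their base-pair union equals
    the union of the input windows; per-line variant positions are pooled.
    """
    ordered = sorted(windows, key=lambda wdw: (wdw.chrom, wdw.start, wdw.end))
    intervals: list[GenomicInterval] = []
    cur: dict | None = None
    for wdw in ordered:
        if cur is not None and wdw.chrom == cur["chrom"] and wdw.start <= cur["end"] + 1:
            cur["end"] = max(cur["end"], wdw.end)
            for line_id, positions in wdw.per_line_positions.items():
                cur["lines"].setdefault(line_id, set()).update(positions)
        else:
            if cur is not None:
                intervals.append(_finish(cur))
            cur = {
                "chrom": wdw.chrom,
                "start": wdw.start,
                "end": wdw.end,
                "lines": {lid: set(ps) for lid, ps in wdw.per_line_positions.items()},
            }
    if cur is not None:
        intervals.append(_finish(cur))
    return intervals


def _finish(cur: dict) -> GenomicInterval:
    return GenomicInterval(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"],
        per_line_variants={
            lid: tuple(sorted(ps)) for lid, ps in sorted(cur["lines"].items())
        },
    )


def overlap_genes(
    intervals: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[tuple[GenomicInterval, str]]:
    """Candidate genes: any CDS segment overlapping any interval by >= 1 bp.

    Deterministic order: (chrom, interval start, gene_id).
    """
    candidates: list[tuple[GenomicInterval, str]] = []
    for interval in intervals:
        for gene in genes:
            if gene.chrom != interval.chrom:
                continue
            if any(
                interval.overlaps(gene.chrom, start, end)
                for start, end in gene.cds_segments
            ):
                candidates.append((interval, gene.gene_id))
    candidates.sort(key=lambda pair: (pair[0].chrom, pair[0].start, pair[1]))
    return candidates


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (0-based half-open) with a comment header."""
    with open(path, "w") as fh:
        fh.write("# candidate intervals (BED3, 0-based half-open)\n")
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start)):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3 back into 1-based inclusive intervals (no per-line detail)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return intervals


def write_report(
    intervals: Sequence[GenomicInterval],
    candidates: Sequence[tuple[GenomicInterval, str]],
    path: str | Path,
) -> None:
    """TSV report: one row per interval with per-line positions and gene hits."""
    gene_hits: dict[tuple[str, int, int], list[str]] = {}
    for interval, gene_id in candidates:
        gene_hits.setdefault((interval.chrom, interval.start, interval.end), []).append(gene_id)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsupporting_lines\tper_line_variants\tcandidate_genes\n")
        for iv in intervals:
            per_line = ";".join(
                f"{lid}:{','.join(map(str, ps))}" for lid, ps in iv.per_line_variants.items()
            )
            genes = ",".join(gene_hits.get((iv.chrom, iv.start, iv.end), []))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.supporting_lines}\t{per_line}\t{genes}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene + CDS features) from a GFF3 file via gffutils."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        segments = tuple(
            sorted(
                (cds.start, cds.end)
                for cds in db.children(gene, featuretype="CDS", order_by="start")
            )
        )
        if not segments:
            logger.warning("gene %s has no CDS features; skipped", gene.id)
            continue
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, cds_segments=segments
        )
        if model.cds_length % 3 != 0:
            logger.warning("gene %s CDS length %d not divisible by 3", gene.id, model.cds_length)
        genes.append(model)
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes
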