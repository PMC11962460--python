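"""Mutagen-spectrum variant filtering for resequenced mutant lines.

Sodium azide (and EMS-class mutagens generally) induce predominantly
G:C->A:T transitions.  When several independently mutagenised lines are
resequenced, restricting each line's homozygous SNV set to that substitution
class removes most background polymorphism and sequencing noise while
retaining essentially every induced causal allele.  This module parses
single-sample VCFs into lightweight :class:`Variant` records and applies the
stringency filter described by :class:`FilterPolicy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: genotype labels carried by :class:`Variant`
HOM_ALT = "hom_alt"
HET = "het"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant owned by one mutant line.

    Coordinates are 1-based on the reference strand, as in VCF.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = HOM_ALT
    depth: int | None = None
    line_id: str = ""

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"ref/alt must be single nucleotides, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")

    @property
    def is_gc_to_at(self) -> bool:
        """True for the azide-spectrum transitions G>A and C>T.

        The complementary-strand events are already covered because VCF
        records are reference-stranded: a C:G -> T:A event on the minus
        strand appears as G>A on the reference.
        """
        return (self.ref == "G" and self.alt == "A") or (
            self.ref == "C" and self.alt == "T"
        )


@dataclass(frozen=True)
class FilterPolicy:
    """Stringency policy applied to a line's variant set.

    transitions_only
        Keep only G>A and C>T substitutions (the dominant sodium-azide class).
    require_homozygous
        Keep only homozygous-alternate calls; selfed mutant lines are expected
        to be homozygous at induced sites.
    min_depth
        Optional read-depth floor; variants with unknown depth are excluded
        when set.
    """

    transitions_only: bool = True
    require_homozygous: bool = True
    min_depth: int | None = None

    def __post_init__(self) -> None:
        if self.min_depth is not None and self.min_depth < 0:
            raise ValueError("min_depth must be >= 0 when set")


DEFAULT_POLICY = FilterPolicy()


def read_vcf(path: str | Path) -> list[Variant]:
    """Read one line's biallelic SNVs from a single-sample VCF.

    Indels, multiallelic records and hom-ref calls are skipped (counted in a
    log message).  The VCF sample name becomes ``line_id``; records with a
    missing genotype are kept with genotype ``"unknown"`` so that a
    homozygosity-requiring policy can exclude them later.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:  # pragma: no cover - pysam message varies
        raise ValueError(f"unreadable VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if len(samples) > 1:
        raise ValueError(f"{path} has {len(samples)} samples; expected one per line")
    line_id = samples[0] if samples else path.stem

    variants: list[Variant] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.alts
        if alts is None or len(alts) != 1:
            n_skipped += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            n_skipped += 1
            continue
        genotype = UNKNOWN
        depth = None
        if samples:
            call = rec.samples[samples[0]]
            gt = call.get("GT")
            if gt is not None and all(a is not None for a in gt):
                if all(a == 1 for a in gt):
                    genotype = HOM_ALT
                elif any(a == 1 for a in gt):
                    genotype = HET
                else:  # hom-ref: not a variant for this line
                    n_skipped += 1
                    continue
            dp = call.get("DP")
            if dp is not None:
                depth = int(dp)
        variants.append(
            Variant(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                genotype=genotype,
                depth=depth,
                line_id=line_id,
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNV/hom-ref records", path, n_skipped)
    return variants


def apply_filter(
    variants: Iterable[Variant], policy: FilterPolicy = DEFAULT_POLICY
) -> list[Variant]:
    """Apply a :class:`FilterPolicy`, preserving input order.

    The result is always a subset of the input; the filter is idempotent and
    tightening any policy field can only shrink the retained set.
    """
    kept: list[Variant] = []
    for v in variants:
        if policy.transitions_only and not v.is_gc_to_at:
            continue
        if policy.require_homozygous and v.genotype != HOM_ALT:
            continue
        if policy.min_depth is not None and (v.depth is None or v.depth < policy.min_depth):
            continue
        kept.append(v)
    return kept


def group_by_line(variants: Iterable[Variant]) -> dict[str, list[Variant]]:
    """Bucket variants by their owning line id (insertion-ordered)."""
    out: dict[str, list[Variant]] = {}
    for v in variants:
        out.setdefault(v.line_id, []).append(v)
    return out


def write_variants_tsv(variants: Sequence[Variant], path: str | Path) -> None:
    """Write variants as a plain TSV (line_id, chrom, pos, ref, alt, genotype, depth)."""
    with open(path, "w") as fh:
        fh.write("line_id\tchrom\tpos\tref\talt\tgenotype\tdepth\n")
        for v in variants:
            depth = "" if v.depth is None else str(v.depth)
            fh.write(
                f"{v.line_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.genotype}\t{depth}\n"
            )
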