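"""Codon-level consequence annotation of CDS substitutions.

Single-base substitutions inside a coding sequence are classified as
synonymous, missense, stop_gained or stop_lost by translating the affected
codon before and after the change with the standard genetic code, and
rendered in the conventional short form (e.g. ``P135L``, ``W321stop``).
Genomic positions are mapped to CDS coordinates strand-aware so that calls
can be made directly on interval-mapping hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .intervalmap import GeneModel
from .varfilter import NUCLEOTIDES

STOP = "*"
_STOP_CODONS = {"TAA", "TAG", "TGA"}

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class CodingSequence:
    """A spliced coding sequence, frame anchored at position 1.

    With ``strict=True`` (the simulator's contract) the sequence must be a
    whole number of codons, start with ATG and contain exactly one stop
    codon, at the end.  Real-world CDS can be loaded with ``strict=False``;
    violations then only warn.
    """

    gene_id: str
    nucleotides: str
    strict: bool = True

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", seq)
        problems = []
        if set(seq) - NUCLEOTIDES:
            raise ValueError(f"{self.gene_id}: non-ACGT characters in CDS")
        if len(seq) % 3 != 0:
            problems.append(f"length {len(seq)} not divisible by 3")
        else:
            if not seq.startswith("ATG"):
                problems.append("does not start with ATG")
            aa = str(Seq(seq).translate())
            if aa.count(STOP) != 1 or not aa.endswith(STOP):
                problems.append("stop codons not exactly one terminal")
        if problems:
            msg = f"{self.gene_id}: " + "; ".join(problems)
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    def __len__(self) -> int:
        return len(self.nucleotides)

    def codon(self, codon_idx: int) -> str:
        return self.nucleotides[(codon_idx - 1) * 3 : codon_idx * 3]


@dataclass(frozen=True)
class CdsVariant:
    """A substitution at a 1-based position within a CDS."""

    cds_pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ValueError("cds_pos is 1-based")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES or self.ref == self.alt:
            raise ValueError(f"invalid substitution {self.ref}>{self.alt}")

    @property
    def label(self) -> str:
        """Mutation-event label, e.g. ``C404T``."""
        return f"{self.ref}{self.cds_pos}{self.alt}"


@dataclass(frozen=True)
class ConsequenceCall:
    codon_index: int
    codon_offset: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str
    short_form: str
    start_codon_affected: bool = False


def codon_index(cds_pos: int) -> tuple[int, int]:
    """Return (codon index, offset within codon), both 1-based."""
    if cds_pos < 1:
        raise ValueError("cds_pos is 1-based")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def _render_aa(aa: str) -> str:
    return "stop" if aa == STOP else aa


def annotate(cds: CodingSequence, variant: CdsVariant) -> ConsequenceCall:
    """Classify a CDS substitution by translating its codon before and after."""
    if variant.cds_pos > len(cds):
        raise ValueError(
            f"{cds.gene_id}: position {variant.cds_pos} beyond CDS length {len(cds)}"
        )
    observed = cds.nucleotides[variant.cds_pos - 1]
    if observed != variant.ref:
        raise ValueError(
            f"{cds.gene_id}: reference mismatch at CDS position {variant.cds_pos}: "
            f"CDS has {observed}, variant claims {variant.ref}"
        )
    idx, offset = codon_index(variant.cds_pos)
    ref_codon = cds.codon(idx)
    alt_codon = ref_codon[: offset - 1] + variant.alt + ref_codon[offset:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        consequence = SYNONYMOUS
    elif alt_aa == STOP:
        consequence = STOP_GAINED
    elif ref_aa == STOP:
        consequence = STOP_LOST
    else:
        consequence = MISSENSE

    start_codon_affected = idx == 1 and consequence is not SYNONYMOUS
    if start_codon_affected:
        warnings.warn(
            f"{cds.gene_id}: substitution in the start codon treated as missense of M1",
            stacklevel=2,
        )
    short_form = f"{_render_aa(ref_aa)}{idx}{_render_aa(alt_aa)}"
    return ConsequenceCall(
        codon_index=idx,
        codon_offset=offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        short_form=short_form,
        start_codon_affected=start_codon_affected,
    )


def map_genomic_to_cds(gene: GeneModel, chrom_pos: int) -> tuple[int, str]:
    """Map a genomic position inside a gene's CDS to a 1-based CDS position.

    Plus-strand genes accumulate segment lengths left-to-right; minus-strand
    genes right-to-left.  Returns ``(cds_pos, strand)``; for minus-strand
    genes the caller must complement the observed ref/alt bases.
    """
    span_start, span_end = gene.span
    inside_span = span_start <= chrom_pos <= span_end
    if gene.strand == "+":
        acc = 0
        for start, end in gene.cds_segments:
            if start <= chrom_pos <= end:
                return acc + (chrom_pos - start + 1), "+"
            acc += end - start + 1
    else:
        acc = 0
        for start, end in reversed(gene.cds_segments):
            if start <= chrom_pos <= end:
                return acc + (end - chrom_pos + 1), "-"
            acc += end - start + 1
    kind = "intronic" if inside_span else "intergenic"
    raise ValueError(
        f"position {chrom_pos} is {kind} with respect to the CDS of {gene.gene_id}"
    )


def annotate_genomic(
    gene: GeneModel, cds: CodingSequence, chrom_pos: int, ref: str, alt: str
) -> ConsequenceCall:
    """Annotate a genomic substitution on a gene, handling strand complement."""
    cds_pos, strand = map_genomic_to_cds(gene, chrom_pos)
    if strand == "-":
        ref, alt = complement(ref), complement(alt)
    return annotate(cds, CdsVariant(cds_pos=cds_pos, ref=ref, alt=alt))


def synthetic_cds(
    gene_id: str,
    planted_codons: Mapping[int, str] | None = None,
    n_codons: int = 200,
    filler: str = "GCT",
) -> CodingSequence:
    """Build a valid CDS with chosen codons planted at given 1-based indices.

    Useful for reconstructing published codon contexts (a mutation event
    plus its reported residue) when the full gene sequence is not to hand.
    Codon 1 is always ATG and the last codon TAA; planted codons may not be
    stops or touch either end.
    """
    planted_codons = dict(planted_codons or {})
    if n_codons < 3:
        raise ValueError("need at least start, one sense codon and stop")
    codons = [filler] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for idx, codon in planted_codons.items():
        if not (1 < idx < n_codons):
            raise ValueError(f"planted codon index {idx} out of range")
        if codon.upper() in _STOP_CODONS or len(codon) != 3:
            raise ValueError(f"invalid planted codon {codon!r}")
        codons[idx - 1] = codon.upper()
    return CodingSequence(gene_id, "".join(codons))


def write_consequence_table(
    rows: Iterable[tuple[str, str, CdsVariant, ConsequenceCall]],
    path: str | Path,
) -> None:
    """Write a mutant-characterisation TSV (gene, mutant, mutation event, aa change)."""
    with open(path, "w") as fh:
        fh.write("gene\tmutant\tmutation_event\tamino_acid_change\tconsequence\n")
        for gene_id, line_id, variant, call in rows:
            fh.write(
                f"{gene_id}\t{line_id}\t{variant.label}\t{call.short_form}\t{call.consequence}\n"
            )
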