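"""Synthetic cohort generator for the mutant-chemotyping pipeline.

Emulates the data structure of a sodium-azide mutagenesis study on a small
diploid genome: a random reference with embedded intron-less coding genes,
per-line homozygous SNV sets dominated by G:C->A:T transitions with exactly
one causal transition per line inside a shared gene, targeted peak-area
tables for the known chemotype classes, and negative-mode MS/MS spectra of
a glycoside/acyl series related by hexosyl / N-methylanthraniloyl / benzoyl
neutral losses.  Every generator is a pure function of (seed, config), so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import consequence as cq
from . import msnetwork as msn
from .intervalmap import GeneModel
from .varfilter import HET, HOM_ALT, Variant

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# non-stop codons used as CDS filler
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)

#: default metabolite panel: the 24 targeted panel compounds plus the four
#: untargeted acyl-sugar / des-acyl markers quantified in group comparisons.
DEFAULT_PANEL: tuple[str, ...] = tuple(f"m{i:02d}" for i in range(1, 29))

#: trace level standing in for "not detected" (LC/MS noise floor, area units)
TRACE = 1.0

_WT_MEANS: dict[str, float] = {
    # end products: avenacins A-1, A-2, B-1, B-2
    "m01": 100.0,
    "m02": 60.0,
    "m03": 40.0,
    "m04": 25.0,
    # pathway intermediates absent from healthy roots
    "m05": TRACE,  # monodeglucosyl avenacin A-1
    "m06": TRACE,  # monodeglucosyl avenacin A-2
    "m11": TRACE,  # des-acyl avenacin A
    "m12": TRACE,  # monodeglucosyl avenacin B
    "m25": TRACE,  # des-acyl monodeglucosyl avenacin A
    "m26": TRACE,  # des-acyl dideglucosyl avenacin A
    # acyl sugars
    "m19": 50.0,  # N-methyl anthranilic acid O-glucoside
    "m27": 40.0,  # benzoic acid O-glucoside
    "m28": 30.0,  # ferulic acid O-glucoside
    # free N-methyl anthranilic acid
    "m20": 15.0,
}
# remaining panel members: early/minor intermediates at a common level
for _m in DEFAULT_PANEL:
    _WT_MEANS.setdefault(_m, 10.0)

_TRITERPENE = tuple(
    m for m in DEFAULT_PANEL if m not in {"m19", "m20", "m27", "m28"}
)


def _profile(**overrides: float) -> dict[str, float]:
    prof = dict(_WT_MEANS)
    prof.update(overrides)
    return prof


#: per-class mean peak areas encoding the published chemotype structure:
#: WT end-products high; sad1 lacking the whole triterpene panel; sad3 and
#: sad7 accumulating their respective glucosylation/acylation substrates;
#: sad4 a hybrid of both with end products and acyl sugars reduced; pal2
#: accumulating 5/6 with benzoyl-dependent products and acyl sugars down
#: (27/28 by 70%, 19 by 17%); cyp94d65 lacking the A-series with the
#: B-series elevated.
DEFAULT_CLASS_PROFILES: dict[str, dict[str, float]] = {
    "WT": _profile(),
    "sad1": _profile(**{m: TRACE for m in _TRITERPENE}),
    # late-glycosylation block: deglucosyl intermediates pile up, plus two
    # side intermediates upstream of the blocked step
    "sad3": _profile(
        m05=60.0, m06=35.0, m12=20.0, m13=50.0, m14=50.0,
        m01=15.0, m02=9.0, m03=6.0, m04=3.8,
    ),
    # acylation block: des-acyl intermediates pile up with their own side
    # intermediates
    "sad7": _profile(
        m11=55.0, m25=30.0, m26=20.0, m21=50.0, m22=50.0,
        m01=15.0, m02=9.0, m03=6.0, m04=3.8,
    ),
    # donor-supply block: hybrid profile — the strong sad3/sad7 markers
    # 5/6/11 accumulate, their minor companions sit just above trace, end
    # products persist at reduced level, all three acyl sugars drop
    "sad4": _profile(
        m05=40.0, m06=28.0, m11=35.0,
        m12=1.3, m25=1.25, m26=1.2,
        m13=15.0, m15=15.0, m16=15.0, m21=15.0,
        m01=60.0, m02=36.0, m03=24.0, m04=15.0,
        m19=20.0, m27=16.0, m28=12.0,
    ),
    # phenylpropanoid-entry block: benzoyl-dependent end products and acyl
    # sugars down (27/28 by 70% > the 65% floor, 19 by 17%), phenolic side
    # intermediates depleted
    "pal2": _profile(
        m05=25.0, m06=15.0,
        m02=12.0, m04=5.0,
        m17=1.0, m18=1.0, m23=40.0,
        m27=12.0, m28=9.0, m19=41.5,
    ),
    # C-23 oxidase block: A-series absent, B-series elevated, with the
    # B-branch side intermediates following
    "cyp94d65": _profile(
        m01=0.0, m02=0.0, m03=100.0, m04=62.5, m07=1.0, m08=1.0, m24=50.0
    ),
}


@dataclass(frozen=True)
class SeriesStep:
    """One member of a neutral-loss series.

    A step with ``parent_mz`` starts a new chain; subsequent steps give the
    loss (a key of the loss library) relative to the previous member.
    """

    name: str
    parent_mz: float | None = None
    loss: str | None = None

    def __post_init__(self) -> None:
        if (self.parent_mz is None) == (self.loss is None):
            raise ValueError(f"{self.name}: give exactly one of parent_mz or loss")


#: avenacin A-1 [M-H]- chain losing two hexoses then the acyl group, plus an
#: A-2 chain losing a hexose then its benzoyl group.
DEFAULT_SPECTRUM_SERIES: tuple[SeriesStep, ...] = (
    SeriesStep("avenacin A-1", parent_mz=1121.5446),
    SeriesStep("monodeglucosyl avenacin A-1", loss="hexosyl"),
    SeriesStep("bisdeglucosyl avenacin A-1", loss="hexosyl"),
    SeriesStep("des-acyl bisdeglucosyl avenacin A", loss="N-methylanthraniloyl"),
    SeriesStep("avenacin A-2", parent_mz=1092.5180),
    SeriesStep("monodeglucosyl avenacin A-2", loss="hexosyl"),
    SeriesStep("des-benzoyl monodeglucosyl avenacin A-2", loss="benzoyl"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults: 2 chromosomes x 5 Mb, 200 intron-less genes of 1-5 kb, 4
    mutant lines with Poisson(150) background homozygous SNVs each, 80% of
    the background drawn from the G:C->A:T azide spectrum, and log-normal
    peak noise with CV 0.15 (triplicate-scale variability).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    min_gene_gap: int = 15_000
    n_lines: int = 4
    background_snvs_per_line: float = 150.0
    p_transition_gc_at: float = 0.8
    het_fraction: float = 0.0
    causal_gene_id: str | None = None
    metabolite_panel: tuple[str, ...] = DEFAULT_PANEL
    class_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_CLASS_PROFILES
    )
    peak_cv: float = 0.15
    spectrum_series: tuple[SeriesStep, ...] = DEFAULT_SPECTRUM_SERIES

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_transition_gc_at <= 1.0):
            raise ValueError("p_transition_gc_at must lie in [0, 1]")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValueError("het_fraction must lie in [0, 1]")
        if min(self.n_chromosomes, self.chrom_length, self.n_genes, self.n_lines) < 1:
            raise ValueError("counts and lengths must be positive")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must be increasing and positive")
        if self.background_snvs_per_line < 0 or self.peak_cv < 0 or self.min_gene_gap < 0:
            raise ValueError("rates and gaps must be non-negative")

    @property
    def line_ids(self) -> tuple[str, ...]:
        return tuple(f"mut{i + 1:02d}" for i in range(self.n_lines))


@dataclass
class Cohort:
    """In-memory result of :func:`simulate_cohort` plus format writers."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    cds_sequences: dict[str, str]
    variants: dict[str, list[Variant]]
    manifest: dict

    @property
    def causal_gene(self) -> GeneModel:
        gid = self.manifest["causal_gene_id"]
        return next(g for g in self.genes if g.gene_id == gid)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.genome.items()}

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in self.genome.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for gene in self.genes:
                start, end = gene.span
                fh.write(
                    f"{gene.chrom}\tsimdata\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                    f"ID={gene.gene_id}\n"
                )
                for i, (s, e) in enumerate(gene.cds_segments, start=1):
                    fh.write(
                        f"{gene.chrom}\tsimdata\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                        f"ID={gene.gene_id}.cds{i};Parent={gene.gene_id}\n"
                    )

    def write_vcfs(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for line_id, variants in self.variants.items():
            path = outdir / f"{line_id}.vcf"
            write_vcf(variants, self.chrom_lengths, line_id, path)
            paths.append(path)
        return paths

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "manifest": outdir / "truth.json",
        }
        self.write_fasta(paths["fasta"])
        self.write_gff3(paths["gff3"])
        self.write_manifest(paths["manifest"])
        for p in self.write_vcfs(outdir / "vcf"):
            paths[p.stem] = p
        return paths


def write_vcf(
    variants: Sequence[Variant],
    chrom_lengths: Mapping[str, int],
    line_id: str,
    path: str | Path,
) -> None:
    """Write one line's variants as a minimal single-sample VCF v4.2."""
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutchemo-simdata\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{line_id}\n")
        for v in ordered:
            gt = "1/1" if v.genotype == HOM_ALT else "0/1"
            fmt, sample = ("GT:DP", f"{gt}:{v.depth}") if v.depth is not None else ("GT", gt)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t{sample}\n")


# ---------------------------------------------------------------------------
# cohort generation


def _random_cds(rng: np.random.Generator, length_nt: int) -> str:
    n_codons = max(length_nt // 3, 4)
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int, int, str]]:
    """Non-overlapping (chrom, start, cds_length, strand) slots, sorted."""
    lo, hi = config.gene_length_range
    placements: list[tuple[str, int, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chroms = sorted(occupied)
    attempts = 0
    while len(placements) < config.n_genes:
        attempts += 1
        if attempts > 100 * config.n_genes:
            raise ValueError("could not place genes without overlap; genome too dense")
        length = int(rng.integers(lo, hi + 1)) // 3 * 3
        length = max(length, 12)
        chrom = chroms[int(rng.integers(len(chroms)))]
        if length + 2 >= config.chrom_length:
            raise ValueError("gene longer than chromosome")
        start = int(rng.integers(2, config.chrom_length - length))
        end = start + length - 1
        # genes are kept more than a window width apart: sliding-window
        # mapping cannot resolve genes closer than that, and the genome this
        # emulates is far sparser than the desk-scale surrogate
        gap = config.min_gene_gap
        if any(s - gap <= end and start <= e + gap for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((chrom, start, length, strand))
    placements.sort(key=lambda p: (p[0], p[1]))
    return placements


def _nonsynonymous_transition_sites(gene: GeneModel, cds: str) -> list[tuple[int, str, str, int]]:
    """Genomic sites whose reference-strand G>A / C>T is non-synonymous.

    Returns (chrom_pos, ref, alt, cds_pos) tuples ordered by position.
    """
    sites = []
    coding = cq.CodingSequence(gene.gene_id, cds)
    start, end = gene.span  # intron-less: single segment
    for chrom_pos in range(start, end + 1):
        cds_pos, strand = cq.map_genomic_to_cds(gene, chrom_pos)
        if (cds_pos - 1) // 3 + 1 == 1:  # leave the start codon alone
            continue
        cds_base = cds[cds_pos - 1]
        ref = cds_base if strand == "+" else cq.complement(cds_base)
        if ref not in "GC":
            continue
        alt = "A" if ref == "G" else "T"
        cds_alt = alt if strand == "+" else cq.complement(alt)
        call = cq.annotate(coding, cq.CdsVariant(cds_pos=cds_pos, ref=cds_base, alt=cds_alt))
        if call.consequence in (cq.MISSENSE, cq.STOP_GAINED):
            sites.append((chrom_pos, ref, alt, cds_pos))
    return sites


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the reference genome, gene annotation and per-line SNV sets.

    Each line carries Poisson-distributed homozygous background SNVs whose
    substitution spectrum is G:C->A:T with probability
    ``p_transition_gc_at``, plus exactly one causal non-synonymous
    G:C->A:T transition at a line-specific CDS position of the shared
    causal gene.  Raises if the causal gene offers fewer usable G/C sites
    than there are lines.
    """
    rng = np.random.default_rng([config.seed, 0])

    # reference genome
    genome_arrays: dict[str, np.ndarray] = {}
    for i in range(config.n_chromosomes):
        genome_arrays[f"chr{i + 1}"] = rng.integers(0, 4, size=config.chrom_length, dtype=np.int8)

    # genes embedded into the reference
    genes: list[GeneModel] = []
    cds_sequences: dict[str, str] = {}
    for idx, (chrom, start, length, strand) in enumerate(_place_genes(config, rng), start=1):
        gene_id = f"g{idx:04d}"
        cds = _random_cds(rng, length)
        gene = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            cds_segments=((start, start + len(cds) - 1),),
        )
        genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
        codes = np.frombuffer(genomic.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int8)
        for k, base in enumerate("ACGT"):
            lut[ord(base)] = k
        genome_arrays[chrom][start - 1 : start - 1 + len(cds)] = lut[codes]
        genes.append(gene)
        cds_sequences[gene_id] = cds

    genome = {
        chrom: _BASES[arr].tobytes().decode("ascii") for chrom, arr in genome_arrays.items()
    }

    gene_ids = [g.gene_id for g in genes]
    causal_id = config.causal_gene_id
    if causal_id is None:
        causal_id = gene_ids[int(rng.integers(len(gene_ids)))]
    elif causal_id not in gene_ids:
        raise ValueError(f"causal_gene_id {causal_id!r} not in generated annotation")
    causal_gene = next(g for g in genes if g.gene_id == causal_id)
    causal_cds = cds_sequences[causal_id]

    sites = _nonsynonymous_transition_sites(causal_gene, causal_cds)
    if len(sites) < config.n_lines:
        raise ValueError(
            f"causal gene {causal_id} has only {len(sites)} usable G/C sites "
            f"for {config.n_lines} lines"
        )
    chosen = rng.choice(len(sites), size=config.n_lines, replace=False)

    variants: dict[str, list[Variant]] = {}
    causal_manifest = {}
    for line_idx, line_id in enumerate(config.line_ids):
        chrom_pos, ref, alt, cds_pos = sites[int(chosen[line_idx])]
        causal = Variant(
            chrom=causal_gene.chrom,
            pos=chrom_pos,
            ref=ref,
            alt=alt,
            genotype=HOM_ALT,
            line_id=line_id,
        )
        call = cq.annotate_genomic(
            causal_gene,
            cq.CodingSequence(causal_id, causal_cds),
            chrom_pos,
            ref,
            alt,
        )
        background = _background_snvs(config, rng, genome, line_id, taken={chrom_pos})
        line_variants = sorted(background + [causal], key=lambda v: (v.chrom, v.pos))
        variants[line_id] = line_variants
        causal_manifest[line_id] = {
            "chrom": causal.chrom,
            "pos": causal.pos,
            "ref": causal.ref,
            "alt": causal.alt,
            "cds_pos": cds_pos,
            "short_form": call.short_form,
            "consequence": call.consequence,
        }

    manifest = {
        "seed": config.seed,
        "causal_gene_id": causal_id,
        "causal_gene_span": list(causal_gene.span),
        "causal_gene_chrom": causal_gene.chrom,
        "causal_gene_strand": causal_gene.strand,
        "causal_variants": causal_manifest,
        "line_ids": list(config.line_ids),
    }
    return Cohort(
        config=config,
        genome=genome,
        genes=genes,
        cds_sequences=cds_sequences,
        variants=variants,
        manifest=manifest,
    )


def _background_snvs(
    config: SimConfig,
    rng: np.random.Generator,
    genome: Mapping[str, str],
    line_id: str,
    taken: set[int],
) -> list[Variant]:
    chroms = sorted(genome)
    n = int(rng.poisson(config.background_snvs_per_line))
    out: list[Variant] = []
    seen: set[tuple[str, int]] = set()
    while len(out) < n:
        # the spectrum coin is held fixed while the position is resampled,
        # otherwise site rejection would deflate the transition fraction
        want_transition = rng.random() < config.p_transition_gc_at
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
            if (chrom, pos) in seen or pos in taken:
                continue
            ref = genome[chrom][pos - 1]
            if want_transition and ref not in "GC":
                continue
            break
        if want_transition:
            alt = "A" if ref == "G" else "T"
        else:
            # any substitution except the azide-spectrum pair
            options = {"A": "CGT", "C": "AG", "G": "CT", "T": "ACG"}[ref]
            alt = options[int(rng.integers(len(options)))]
        genotype = HET if rng.random() < config.het_fraction else HOM_ALT
        seen.add((chrom, pos))
        out.append(
            Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype, line_id=line_id)
        )
    return out


# ---------------------------------------------------------------------------
# peak tables


def simulate_peak_table(
    config: SimConfig,
    class_assignments: Mapping[str, str],
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Log-normal peak areas around each line's class-profile means.

    Rows are (line_id, replicate); columns are the metabolite panel plus
    the metadata columns.  ``n_replicates=0`` gives an empty table with the
    full header.  Unknown class labels fail naming the offending line.
    """
    for line_id, label in class_assignments.items():
        if label not in config.class_profiles:
            raise ValueError(f"line {line_id!r} has unknown chemotype class {label!r}")
    rng = np.random.default_rng([config.seed, 1])
    cv = config.peak_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for line_id, label in class_assignments.items():
        profile = config.class_profiles[label]
        means = np.array([profile.get(m, 0.0) for m in config.metabolite_panel])
        for rep in range(1, n_replicates + 1):
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=means.size)
            areas = means * noise
            rows.append([line_id, rep, label, *areas])
    columns = ["line_id", "replicate", "class_label", *config.metabolite_panel]
    table = pd.DataFrame(rows, columns=columns)
    for m in config.metabolite_panel:
        table[m] = table[m].astype(float)
    return table


# ---------------------------------------------------------------------------
# MS/MS spectra


def simulate_spectra(
    config: SimConfig,
    losses: Mapping[str, float] | None = None,
    n_shared_fragments: int = 6,
) -> list[msn.Spectrum]:
    """Generate negative-mode [M-H]- spectra for the configured loss series.

    Each chain starts at a parent ion; derivatives shift the precursor by
    the configured neutral-loss mass.  Members of a chain share a block of
    identical scaffold fragments (direct cosine matches) plus
    precursor-tracking fragments that move with the precursor (matched via
    the modified-cosine shift), so adjacent members exceed the default
    network threshold.  A couple of member-specific peaks and one
    sub-threshold peak per spectrum exercise noise filtering.
    """
    if not config.spectrum_series:
        raise ValueError("spectrum_series must be non-empty")
    losses = msn.DEFAULT_LOSSES if losses is None else dict(losses)
    rng = np.random.default_rng([config.seed, 2])

    spectra: list[msn.Spectrum] = []
    chain_fragments: np.ndarray | None = None
    chain_fragment_intensity: np.ndarray | None = None
    precursor: float | None = None
    for step in config.spectrum_series:
        if step.parent_mz is not None:
            precursor = float(step.parent_mz)
            lo, hi = 120.0, precursor - 250.0
            chain_fragments = np.sort(rng.uniform(lo, hi, size=n_shared_fragments))
            chain_fragment_intensity = rng.uniform(200.0, 1000.0, size=n_shared_fragments)
        else:
            if precursor is None:
                raise ValueError(f"{step.name}: loss step before any chain parent")
            if step.loss not in losses:
                raise ValueError(f"{step.name}: unknown loss {step.loss!r}")
            precursor = precursor - losses[step.loss]
        assert chain_fragments is not None and chain_fragment_intensity is not None
        tracking_mz = precursor - np.array([46.0054, 60.0211, 120.0423])
        tracking_intensity = np.array([400.0, 300.0, 250.0])
        unique_mz = rng.uniform(120.0, precursor - 150.0, size=2)
        unique_intensity = rng.uniform(50.0, 150.0, size=2)
        noise_mz = rng.uniform(120.0, precursor - 150.0, size=1)
        noise_intensity = np.array([10.0])  # below the default intensity floor
        mz = np.concatenate([chain_fragments, tracking_mz, unique_mz, noise_mz])
        intensity = np.concatenate(
            [chain_fragment_intensity, tracking_intensity, unique_intensity, noise_intensity]
        )
        spectra.append(
            msn.Spectrum(
                spectrum_id=step.name,
                precursor_mz=round(precursor, 4),
                mz=np.round(mz, 4),
                intensity=np.round(intensity, 1),
                polarity="negative",
            )
        )
    return spectra
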