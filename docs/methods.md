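# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical corner cases.

## Mutagen-spectrum filtering

Sodium azide mutagenesis produces predominantly G:C→A:T transitions. The
filter keeps reference-stranded substitutions G→A and C→T; the
complementary-strand events need no special handling because VCF records are
reference-stranded (a minus-strand G→A appears as C→T). The default policy
additionally requires homozygous-alternate genotypes — selfed mutant lines
are expected to be homozygous at induced sites — and leaves the read-depth
floor unset because depth conventions vary by caller. Variants with an
unknown genotype are excluded under the homozygosity requirement, and
variants with unknown depth are excluded whenever a depth floor is set
(conservative in both cases). The filter is idempotent and monotone:
tightening any field can only shrink the retained set.

## Sliding-window intersection mapping

With several independently mutagenised lines sharing a phenotype, the causal
gene is located as the genomic region where *every* line carries a filtered
variant. Windows of `window_size` (default 10 kb) are enumerated at offsets
1, 1+step, … per chromosome (`step` defaults to 1 kb, a 10:1
window-to-step ratio that makes grid effects negligible; it is exposed as a
flag because only the window width, not the step, is a published parameter).
Variants need not be at shared positions — independent alleles hit different
sites of the same gene. `min_lines` defaults to `"all"`; an integer
relaxation is available for cohorts suspected to contain a mis-binned line.
Qualifying windows that overlap or abut are merged into maximal intervals;
a gene is a candidate when any CDS segment overlaps any interval by ≥ 1 bp.
Internal coordinates are 1-based inclusive (VCF/GFF convention); BED export
converts to 0-based half-open.

Two geometric facts matter when interpreting results. First, a merged causal
interval is up to `2·window_size − allele spread` wide (~17 kb at defaults),
so the method cannot resolve genes closer together than about one window
width. Second, background variants produce *coincidence windows* — spans in
which every line happens to carry a background variant. At the generator's
default densities (~120 retained variants per line on 10 Mb, 4 lines) the
expected number of qualifying background offsets is
`n_offsets · (1 − e^{−λw})^L ≈ 10⁴ · 0.114⁴ ≈ 1.7` per cohort, which merges
into roughly 0.3–0.5 spurious intervals per run, about a third of which
overlap some gene. Exact single-candidate resolution therefore occurs in
~80–90 % of cohorts at these densities; the causal gene itself is recovered
essentially always, and every spurious candidate is auditable as a
coincidence (each line shows ≥ 1 background variant in the interval). Real
screens mitigate this with sparser genomes, more lines, or by triaging
candidates with the consequence calls.

## Consequence annotation

For a CDS substitution at 1-based position *p*, the codon index is
⌊(p−1)/3⌋+1 and the offset within the codon ((p−1) mod 3)+1. The reference
and mutated codons are translated with the standard genetic code (the code
table is the only one used; plant nuclear genes need no other) and the call
is classed synonymous / missense / stop_gained / stop_lost. Short forms
render stops as `stop` (`W321stop`) while structured fields carry `*`.
Start-codon substitutions are reported as missense of M1 with a warning
flag rather than a dedicated class. Genomic positions map to CDS
coordinates strand-aware (plus strand accumulates segment lengths
left-to-right, minus strand right-to-left); for minus-strand genes the
caller's ref/alt bases are complemented before annotation. Positions inside
the gene span but outside CDS segments raise an "intronic" error, positions
outside the span "intergenic".

## Chemotype classification

Peak tables hold non-negative LC/MS peak areas, one row per (line,
replicate), columns `m01…` for the metabolite panel. Columns are
mean-centred and scaled to unit variance (autoscaling — the default of the
multivariate software this emulates; a `log10(area+1)` transform is
available but off by default) and the two leading principal components are
extracted. Zero-variance columns are dropped with a warning. A line is
placed at the mean of its replicate scores and assigned to the nearest
reference-centroid by Euclidean distance in PC space; it is *novel* when
that distance exceeds `threshold_factor` (default 3) times the median
within-reference replicate-to-centroid distance. The factor 3 is a
convention — the source analysis called an outlier line "clearly distinct"
without stating a criterion — and errs toward flagging: in simulation ~2–3 %
of correctly-centred lines exceed it.

Marker ranking uses the Welch (unequal-variance) *t* statistic, descending
by |t| with |log₂ fold change| as tie-break, because the published marker
selection does not state its statistic and Welch is the safer default for
heteroscedastic peak areas. Pairwise group comparisons use the classical
equal-variance Student *t* (the statistic the figure legends name). With
zero variance in both groups the comparison returns p = 1 when means agree
and p = 0 otherwise. Segregation of F2 genotype counts is tested with a
Pearson χ² goodness of fit against the stated ratio (df = classes − 1); for
a 1:2:1 ratio at n = 192, ~95 % of true-ratio cohorts are judged consistent
at α = 0.05.

## Molecular networking

Spectra are preprocessed by removing peaks below an absolute intensity of
25 (the convention of the networking platform whose thresholds we adopt;
the unit is instrument-dependent), square-root transforming the remaining
intensities (standard practice to tame dominant peaks; a flag disables it)
and L2-normalising. The modified cosine between preprocessed spectra
considers a peak pair matchable when its m/z difference is within the
fragment tolerance either directly or after subtracting the precursor
difference; a one-to-one matching is built greedily in descending
intensity-product order. Greedy matching is what common implementations use;
an exhaustive-matching oracle in the test suite confirms it attains the
optimum on every generated ≤ 6-peak instance (the greedy score can in
principle fall below the optimum; no counterexample arose in testing).
Scores are symmetric, bounded by [0, 1], and reduce to the plain cosine at
Δ = 0.

Networks keep edges with cosine ≥ 0.6 and ≥ 3 matched peaks and drop
connected components below 2 nodes. Within a component, nodes whose
precursor m/z agree within 0.01 Da are isomer candidates; only the
highest-total-intensity member survives and the induced subgraph is
re-filtered. Edge precursor deltas are compared to the neutral-loss library
— hexosyl 162.0528 (C₆H₁₀O₅), *N*-methylanthraniloyl 133.0528 (C₈H₇NO),
benzoyl 104.0262 (C₇H₄O), monoisotopic masses computed from the formulas —
within 0.1 Da; the nominal (rounded) loss is reported alongside. Deltas are
taken directly between [M−H]⁻ m/z values since losses between like-charged
deprotonated ions equal neutral-fragment masses. Topological edge pruning
(top-K neighbours), library identification and consensus clustering are out
of scope.

## The synthetic cohort generator

All generators are pure functions of `(seed, config)` (independent
deterministic streams per generator), so identical configurations are
byte-identical across runs.

**Genome and variants.** Defaults: 2 chromosomes × 5 Mb of uniform random
sequence, 200 intron-less genes of 1–5 kb placed non-overlapping with a
minimum inter-gene gap of 15 kb, 4 mutant lines, Poisson(150) homozygous
background SNVs per line of which 80 % are drawn from the G:C→A:T azide
spectrum, and exactly one causal non-synonymous G:C→A:T transition per line
at a line-specific CDS position of a shared causal gene. The gene gap keeps
genes more than one mapping window apart: the real genome this surrogate
stands in for is two orders of magnitude sparser, and without the gap the
mapping stage would be asked to separate genes it geometrically cannot.
CDSs are whole codons with an ATG start and single terminal stop; the
density parameters are desk-scale surrogates (the source study does not
report per-line SNV counts) chosen dense enough that coincidence handling is
actually exercised. Heterozygous contamination is available as an optional
fraction for filter testing. What is *not* emulated: shared parental
polymorphism between lines, sequencing error, depth variation, indels,
introns and splice effects.

**Peak tables.** Log-normal noise (CV 0.15, matching triplicate-scale
variability) around per-class mean profiles. "Absent" metabolites sit at a
trace mean of 1.0 area unit — an LC/MS detection floor — rather than exactly
zero, except where a class is defined by a hard absence (metabolites 1–2 in
the C-23 oxidase mutant class). The profiles encode the published class
structure: WT high in end products 1–4; sad1 lacking the whole triterpene
panel; sad3 accumulating deglucosyl intermediates 5/6/12; sad7 accumulating
des-acyl intermediates 11/25/26; sad4 a hybrid with 5/6/11 strongly
accumulating, end products present but reduced, and all three acyl sugars
(19, 27, 28) reduced; pal2 with benzoyl-dependent products down (27/28 by
70 %, 19 by 17 % — means set from the published percentages); cyp94d65 with
the A-series absent and the B-series elevated. The otherwise-unconstrained
panel members (m07–m10, m13–m18, m21–m24) carry per-class side-intermediate
signatures of moderate amplitude; they exist so that seven classes are
separable in a two-component score plane (a handful of metabolites per class
cannot spread seven centroids once the sad1 axis has claimed PC1) while
staying weak enough that the designed sad4 discriminants (5, 6, 11, 19, 27,
28) dominate the Welch ranking. Because the noise is multiplicative, any
strong accumulation saturates at t ≈ √n/CV regardless of its mean, so the
designed marker ordering is encoded through the *ratio* structure, not raw
magnitudes. Amplitudes were fixed by simulation during design (marker top-1
in the designed set in ~97 % of cohorts over 200 seeds; class-label
recovery ~96 % over 60 seeds) and are not tuned thereafter.

**Spectra.** Each configured series chain starts from a parent [M−H]⁻ ion
and steps down by library losses. Chain members share a block of identical
scaffold fragments (direct matches) plus precursor-tracking fragments at
fixed offsets below the precursor (matched only through the modified-cosine
shift), two member-specific peaks, and one sub-threshold peak to exercise
intensity filtering. Adjacent members exceed the default cosine/matched-peak
gates by construction.

## Problem sizes used in testing

Oracle-based checks run at sizes where the oracle is exact: exhaustive
matching on ≤ 6-peak spectra, per-offset window rechecks on 100-kb toy
genomes, full retranslation of 60-nt CDSs. Recovery rates are estimated
over 20 seeds at the full default cohort scale (10-Mb genome), and the
segregation calibration over 2 000 simulated F2 cohorts of 192.

## Known limitations

* Interval mapping reports coincidence intervals at high background density
  (quantified above) and cannot separate genes closer than one window.
* Greedy peak matching is not provably optimal, only empirically so on the
  tested instance sizes.
* The chemotype classifier operates in two components by design; classes
  whose separation lives outside that plane would need more components.
* The generator's profiles are stylised: real peak tables have correlated
  noise, batch effects and missing values, none of which are modelled, so
  passing recovery tests demonstrates the pipeline's logic, not its power
  on real instrument data.
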