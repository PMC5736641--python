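# Methods

## Scope and model

`fusionviz` annotates and visualizes gene-fusion candidates that have
already been called from RNA-seq; it neither detects fusions nor runs
alignment/quantification. Its unit of work is one BEDPE row: two genomic
breakpoints with strands and an ordered gene pair (`GENE5>>GENE3`), which
it turns into (i) a chimeric transcript model, (ii) a frame call and a
chimeric protein with remapped domains, and (iii) expression views at the
exon and cohort level.

## Coordinate and format conventions

All genomic intervals are held 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted at parse time. Amino-acid
coordinates are 1-based inclusive (UniProt/Pfam convention). Chromosome
names are harmonized between BEDPE/GTF/FASTA/BAM by normalizing the `chr`
prefix at load time, since mixed-reference inputs are the most common user
failure.

BEDPE breakpoints: callers in this dialect encode single-base breakpoints
as 1-bp intervals. When an interval is wider, the breakpoint base is the
interval end nearest the junction on the transcription strand (5′ partner:
`end−1` on `+`, `start` on `−`; 3′ partner mirrored), which degrades
gracefully for imprecise calls. The BEDPE standard has no mandated columns
for supporting reads or sample ids; this package's contract is a header
comment naming trailing columns `spanning`/`encompassing`/`sample`.
Without such a header, counts default to 0 and the structure plot draws no
read glyphs.

## Isoform selection

"Representative isoform" is deliberately expression-free so that a GTF
alone suffices: a GTF `tag` containing `canonical` wins; else the longest
CDS; else the longest spliced transcript; final ties break on the
lexicographically smallest accession. The choice is deterministic and
user-overridable per partner (`--tx5/--tx3`). Plots are produced for every
viable isoform pair (breakpoint inside both hulls), with the
representative pair first.

## Fusion transcript assembly

The 5′ partner retains all exonic sequence from transcription start up to
and including the breakpoint base; the 3′ partner from its breakpoint base
to transcription end. The breakpoint base is retained on both sides — the
two breakpoints are distinct genomic positions, so nothing is double
counted. Reverse-strand partners are spliced in transcription order via
reverse complement. Intronic breakpoints (frequent when the underlying
event is genomic) are snapped to the nearest retained-side exon boundary
— 5′ role: end of the last fully upstream exon; 3′ role: start of the next
downstream exon — with a warning and a "junction snapped" annotation in
the plot, rather than an error. A `.` strand defers to the GTF model; an
explicit strand contradicting the model is an error, never a silent
override.

## Frame, translation, domains

Translation starts at the 5′ partner's annotated start codon. With
`r` = retained 5′ coding nt and `o` = the junction's offset within the 3′
partner's own spliced CDS, the fusion is in frame iff `(r − o) mod 3 = 0`
and no stop codon occurs in a codon fully upstream of the junction.
Standard genetic code only (stop set TAA/TAG/TGA); ambiguous (N) codons
translate to X and are logged. If the 5′ breakpoint lies in the 5′ UTR the
fusion is reported untranslated by the 5′ partner (`no_cds`,
`junction_in_5'UTR`); no alternative-ATG scanning is attempted, because
that would invent biology the inputs do not support.

Domain remapping: 5′ domains keep their native coordinates and are clipped
at the junction residue; 3′ domains (in-frame only) shift by
`Δ = (r − o)/3` residues and are clipped to the fully-3′-derived region.
Domains partially cut by the junction or termination are kept with
`retained_fraction < 1` rather than dropped — partial domain loss is
exactly what the plot is meant to show. Out-of-frame fusions get no 3′
domains, and the plot draws the post-junction region as a white box ending
in a red cross at the termination site. When the junction codon is hybrid
(`r mod 3 ≠ 0`), that residue is attributed to the 5′ side and fully
native 3′ residues start at the next position.

## Expression

Coverage is raw per-base depth (not normalized): the exon-expression plot
compares exons within one sample, where raw depth is what a pileup shows.
Only aligned (M/=/X) bases of primary, non-duplicate, non-supplementary
alignments count; the MAPQ threshold defaults to 0 and is configurable.
Cohort expression is FPKM (`count · 10⁹ / (length · column total)`) because
FeatureCounts gene counts plus lengths are the expected input; the unit
label is configurable. Fusion-positive flags match the ordered pair name
exactly — the reciprocal fusion is a different event.

## Rendering

Fixed default palette: blue = 5′ partner, red = 3′ partner, red junction
lines, blue exon-boundary lines; overridable via a key=value style file.
Read glyphs saturate at 3 (1 / 2–10 / >10 supporting reads → 1 / 2 / 3
glyphs; zero reads draw none). Y-axes auto-scale to the smallest
1/2/5 × 10^k value at or above the observed maximum, overridable with
`--ymax`; all-zero tracks render flat with y-max 1 and a warning. Cohort
bars are sorted by the 3′ gene's expression (a presentation choice; any
stable order would do; ties break on sample id). Output files are named
`<fusion>.<tx5>.<tx3>.<plot>.pdf` so per-isoform-pair outputs never
collide. All renderers are deterministic and PDFs are written without a
creation timestamp, so identical inputs give byte-identical files.

## Toy data generator

`fixtures.make_scenario` writes a complete input set (FASTA+fai, GTF,
sorted+indexed BAM, single-sample and cohort BEDPE, domain and ideogram
TSVs, count matrix) from a seed, deterministically. The planted design:
two genes on kilobase-scale chromosomes — a 3-exon 5′ partner (405-nt
spliced, 300-nt CDS) cut inside exon 2, and a 5-exon 3′ partner (474-nt
spliced, 360-nt CDS) joined at the start of its exon 4 — with a second 5′
isoform (shorter CDS) and a short non-coding 3′ isoform whose hull
excludes the breakpoint, so isoform selection and viability filtering are
exercised. Defaults reproduce the classic prostate-cancer deletion
geometry: both partners on the reverse strand of one chromosome, the
fused 3′ exons covered at 4-fold elevated read depth (8 vs 32 reads per
exon plus splice-junction, soft-clipped, duplicate and secondary reads),
a 12-sample cohort with one third fusion-positive samples over-expressing
the 3′ gene 5-fold, and planted supporting-read counts (7 spanning, 12
encompassing). CDS sequences are stop-free random codons between ATG and
TAA, so frame outcomes are fully controlled by the planted breakpoint
phase (`s5 = 239` in-frame, `240` frameshift).

Every truth the generator reports (expected cDNA, junction offset, frame,
peptide, remapped domains, per-exon depth, FPKM) is computed by its own
arithmetic — a spliced-coordinate walk and a codon-table translation over
the planted sequences, and depth accumulated while emitting reads — not
by the annotation pipeline, so integration tests compare two independent
routes. What the toys do not emulate: sequencing error, soft-clip
realism, alternative splicing beyond the planted isoforms, realistic
intron/intergenic sizes, or biological variance in the cohort counts.
Passing tests therefore demonstrate correctness of the coordinate,
frame and normalization arithmetic, not robustness to noisy real-world
alignments.

## Problem sizes and numerical choices

Tests and the acceptance script run entirely on generated toys: ~100
random fusions for the cDNA oracle, 60 for frame/translation, 50 domain
placements, 20 random BAMs for the pileup oracle — sizes chosen so the
whole suite completes in seconds while exercising all four strand
combinations and every CIGAR class the coverage code distinguishes.
Sequence comparisons are exact string equality; FPKM comparisons use
1e-9 absolute or 1e-12 relative tolerance (pure floating-point
arithmetic); no other numerical tolerances exist in the package.

## Known limitations

Single-isoform fusion models only (no splice-graph reconstruction);
GTF only (no GFF3); no statistical test for the cohort contrast (the plot
draws it; inference is out of scope); no handling of multi-GB streaming
inputs; read-through/cis-splicing classification and breakpoint
refinement are out of scope.
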