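# fusionviz

Annotation and publication-quality visualization of gene fusions from
standard RNA-seq inputs.

## The problem

Fusion callers emit lists of candidate events — two genomic breakpoints, a
pair of partner genes, some supporting reads — but deciding whether a
candidate matters biologically requires answering three further questions:
What does the chimeric transcript look like? Does it encode a protein, and
with which domains? Does the fusion change expression of either partner,
in this sample and across a cohort? `fusionviz` automates those
annotation steps and renders them as four PDF figures, so that
prioritizing fusions no longer requires manual inspection in a genome
browser. It is aimed at cancer transcriptomics analysts who already have
caller output (BEDPE), gene models (GTF), a genome (FASTA) and alignments
(BAM).

## What it computes

**Fusion transcript.** For each candidate, a representative isoform of each
partner is selected (canonical tag, else longest CDS, else longest spliced
length, ties broken by accession). The 5′ partner contributes all exonic
sequence from its transcription start through the breakpoint base; the 3′
partner from its breakpoint base to its transcription end. Reverse-strand
partners are read in transcription order via reverse complement; intronic
breakpoints snap to the nearest retained-side exon boundary. The chimeric
cDNA is their concatenation, with the junction offset *j* equal to the 5′
retained length.

**Reading frame.** With *r* = retained 5′ coding nucleotides (junction
offset minus the 5′ start-codon offset) and *o* = the junction's offset
within the 3′ partner's own CDS, the fusion is **in frame** iff

    (r − o) ≡ 0 (mod 3)

and translation from the 5′ start codon reaches the junction without a
premature stop; otherwise it is out of frame and terminates at the first
stop codon in the shifted frame. In-frame fusion proteins are the 5′
native prefix followed by the 3′ native suffix; partner domains
(1-based amino-acid intervals) are remapped by identity (5′, clipped at
the junction) or by the shift Δ = (r − o)/3 (3′, clipped to the retained
region), each with its retained fraction.

**Expression.** Per-base read depth over each partner's hull is computed
from the BAM counting aligned (M/=/X) bases of primary, non-duplicate
alignments. Cohort expression is FPKM,
`count · 10⁹ / (gene_length · library_size)`, from a FeatureCounts-style
count matrix, with samples flagged fusion-positive when their candidate
list contains the ordered `GENE5>>GENE3` pair.

**Plots.** (1) structure: ideogram, partner gene tracks, fused transcript
and supporting-read glyphs (1, 2 or 3 glyphs for 1, 2–10 or >10 reads);
(2) domain: the chimeric protein with remapped domains, N/C termini
labelled, out-of-frame 3′ regions drawn as a white box ending in a red
cross at the termination site; (3) exon expression: depth curves with red
junction and blue exon-boundary lines, auto-scaled axes; (4) cohort
expression: per-sample bars for both genes, fusion-positive samples
highlighted. Blue consistently marks the 5′ partner, red the 3′ partner.

## Worked example

No external data is needed — the package generates complete toy datasets
with planted ground truth:

```bash
fusionviz make-fixtures --out-dir toy --seed 1
fusionviz all --bedpe toy/fusions.bedpe --gtf toy/annotation.gtf \
    --fasta toy/genome.fa --bam toy/sample.bam --domains toy/domains.tsv \
    --ideogram toy/ideogram.tsv --counts toy/counts.tsv --sample S01 \
    --out-dir out
```

or, from Python, `python examples/annotate_fusion.py`, which prints:

```
fusion           GENEA>>GENEB
isoform pair     TXA001 x TXB001
junction exons   2 (5') / 4 (3')
cDNA             423 nt, junction at offset 240
frame            in_frame
protein          104 aa, junction at aa 60
  domain HELX       aa 5-30 (retained 100% of native)
  domain SER-PROT   aa 40-60 (retained 41% of native)
  domain ETS        aa 70-100 (retained 100% of native)
```

The fusion joins exon 2 of the 5′ partner to exon 4 of the 3′ partner; 240
of the 423 cDNA nucleotides come from the 5′ side; the junction preserves
the 3′ reading frame, so the 104-aa chimeric protein carries the 3′
partner's ETS domain intact while the 5′ SER-PROT domain is cut at the
junction (41 % retained). `examples/expression_views.py` and
`examples/glyph_rule.py` demonstrate the coverage/cohort computations and
the read-glyph binning the same way.

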