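"""Annotate one gene fusion end to end on a generated toy dataset.

Builds a self-contained toy genome/GTF/BEDPE with a planted reverse-strand
fusion, reconstructs the chimeric transcript, infers the reading frame,
translates the fusion protein and remaps the partner domains.
"""

import tempfile
from pathlib import Path

import pyfaidx

from fusionviz import (
    fixtures,
    fusion_builder,
    gene_models,
    io_formats,
    protein_annotation,
)

with tempfile.TemporaryDirectory() as tmp:
    sc = fixtures.make_scenario(seed=1, out_dir=Path(tmp) / "toy")
    store = gene_models.parse_gtf(str(sc.paths["gtf"]))
    genome = pyfaidx.Fasta(str(sc.paths["fasta"]))

    rec = io_formats.read_bedpe(sc.paths["bedpe"])[0]
    candidate = fusion_builder.candidate_from_bedpe(rec, store)
    five, three = fusion_builder.enumerate_isoform_pairs(candidate, store)[0]
    ft = fusion_builder.build_fusion_transcript(candidate, five, three, genome)
    fs = protein_annotation.determine_frame(ft)
    fp = protein_annotation.translate_fusion(ft, fs)
    domains = io_formats.read_domain_table(sc.paths["domains"])
    fp.domains = protein_annotation.remap_domains(fp, fs, domains, five, three)

    print(f"fusion           {candidate.name}")
    print(f"isoform pair     {five.transcript_id} x {three.transcript_id}")
    print(f"junction exons   {gene_models.exon_ordinal(five, candidate.five_pos)}"
          f" (5') / {gene_models.exon_ordinal(three, candidate.three_pos)} (3')")
    print(f"cDNA             {len(ft.cdna)} nt, junction at offset "
          f"{ft.junction_offset}")
    print(f"frame            {fs.status}")
    print(f"protein          {len(fp.peptide)} aa, junction at aa {fp.junction_aa}")
    for d in fp.domains:
        print(f"  domain {d.name:10s} aa {d.start_aa}-{d.end_aa} "
              f"(retained {d.retained_fraction:.0%} of native)")

# The cDNA length is the sum of the retained exonic lengths of both
# partners; "in_frame" means the 3' partner's codons keep their native
# phase after the junction, so the domains after it are genuine native
# domains of the 3' gene shifted into fusion-protein coordinates.
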