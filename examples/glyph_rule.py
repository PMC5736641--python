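"""The supporting-read glyph rule used by the structure plot.

To conserve space the structure plot never draws more than three read
glyphs: 1 supporting read draws 1 glyph, 2-10 reads draw 2, and more than
10 draw 3.
"""

from fusionviz import glyph_count

for n in (0, 1, 2, 7, 10, 11, 25, 100):
    print(f"{n:>4} supporting reads -> {glyph_count(n)} glyph(s)")

# The glyph count is a monotone, saturating summary of read support, not a
# measurement: past 10 reads the plot communicates only "well supported".
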