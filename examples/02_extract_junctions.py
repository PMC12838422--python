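"""Derive the exonic splice-junction flank positions d1-d3 / a1-a3 from a GTF.

d1 is the last coding base of an exon that donates a splice site, a1 the
first coding base of an exon that accepts one; labels and reference bases
are reported on the coding strand.
"""

from pathlib import Path

from spliceflank.junctions import parse_gtf, sites_from_annotation, write_sites_bed
from spliceflank.signatures import background_composition
from spliceflank.simulate import SimulationConfig, generate_annotation, generate_genome

config = SimulationConfig(seed=42, n_genes=120)
genome = generate_genome(config)
Path("scratch").mkdir(exist_ok=True)
gtf = generate_annotation(config, genome, "scratch/example.gtf")

transcripts = parse_gtf(str(gtf))
index = sites_from_annotation(transcripts, genome)
write_sites_bed(index, "scratch/example_sites.bed")

print(f"{len(transcripts)} protein-coding transcripts -> {len(index):,} non-redundant sites")
composition = background_composition(index)
for label in ("d1", "d2", "a1", "a2"):
    top = composition.fractions.loc[label].idxmax()
    frac = composition.fraction(label, top)
    print(f"  {label}: most frequent base {top} ({100 * frac:.1f}%)")
# d1 should be ~80% G and a1 ~49% G: the exonic splice consensus the
# generator plants and real GENCODE annotation shows.
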