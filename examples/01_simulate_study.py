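"""Generate a small synthetic study: genome, annotation, variants, tables.

The generator plants the structure the analysis is built to measure: an
exonic consensus at the six flank positions (G-rich d1/a1), a G>T / G>A
dominated substitution spectrum at d1, a 78/22 missense/silent mixture, and
low-LOEUF enrichment among the genes that carry recurrent cancer variants.
"""

from pathlib import Path

from spliceflank.simulate import SimulationConfig, simulate_all

outdir = Path("scratch/example_study")
config = SimulationConfig(
    seed=42,
    n_genes=60,
    n_variants_per_dataset={"cosmic": 2000, "gnomad": 1200},
)
artifacts = simulate_all(config, outdir)

print(f"wrote {len(artifacts['paths'])} files to {outdir}/")
genome = artifacts["genome"]
print(f"contig length: {len(genome.contigs['chrS']):,} bp, genes: {len(genome.genes)}")
print(f"junction flank sites: {len(genome.junction_sites()):,}")
truth = artifacts["truth"]
n_junction = sum(1 for t in truth.variants["cosmic"] if t["is_junction"])
print(f"cosmic variants on junction flanks: {n_junction} of {len(truth.variants['cosmic'])}")
# Every emitted file is plain text (FASTA/GTF/VCF/TSV/JSON); ground_truth.json
# records exactly what was planted, so downstream recovery can be verified.
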