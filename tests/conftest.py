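import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from spliceflank.pipeline import RunConfig, run_pipeline
from spliceflank.simulate import SimulationConfig, generate_genome, generate_variants, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_genes=40,
        n_variants_per_dataset={"cosmic": 1500, "gnomad": 1000},
    )


@pytest.fixture(scope="session")
def small_sim(small_config, tmp_path_factory):
    """One small simulated study, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("small_sim")
    artifacts = simulate_all(small_config, outdir)
    artifacts["outdir"] = outdir
    return artifacts


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    """Full pipeline run on the small study (fresh simulation, same seed)."""
    outdir = tmp_path_factory.mktemp("small_run")
    config = RunConfig(
        out_dir=outdir, seed=7, simulate=True, sim_config=small_config
    )
    summary = run_pipeline(config)
    return {"outdir": outdir, "summary": summary, "config": config}


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Pipeline run at the study scale: 500 genes, 20,000 variants."""
    outdir = tmp_path_factory.mktemp("study_run")
    sim = SimulationConfig(seed=11)
    config = RunConfig(out_dir=outdir, seed=11, simulate=True, sim_config=sim)
    summary = run_pipeline(config)
    return {"outdir": outdir, "summary": summary, "sim": sim}


@pytest.fixture(scope="session")
def study_materials(study_run):
    """In-memory objects rebuilt from the study-scale run's intermediates."""
    import pandas as pd

    from spliceflank.junctions import read_sites_bed
    from spliceflank.pipeline import annotated_from_frame
    from spliceflank.simulate import GroundTruth

    outdir = study_run["outdir"]
    frame = pd.read_csv(outdir / "annotated.tsv", sep="\t", dtype={"contig": str})
    return {
        "annotated": annotated_from_frame(frame),
        "sites": read_sites_bed(str(outdir / "sites.bed")),
        "truth": GroundTruth.from_json(outdir / "inputs" / "ground_truth.json"),
        "outdir": outdir,
        "sim": study_run["sim"],
        "summary": study_run["summary"],
    }


@pytest.fixture()
def toy_genome():
    """Two tiny transcripts (one per strand) with hand-checkable coordinates."""
    from spliceflank.junctions import TranscriptModel

    #           0         1         2         3         4
    #           0123456789012345678901234567890123456789012345
    contig = "ATGAAAGGTAAGCCCCTTTTTAGGACGAGTTTGGCCAAGGTTCCAA"
    plus = TranscriptModel(
        transcript_id="T+",
        gene_id="GP",
        gene_name="GP",
        contig="c1",
        strand="+",
        exons=[(0, 9), (21, 30)],
        cds=[(0, 9), (21, 30)],
        canonical_flag=True,
    )
    minus = TranscriptModel(
        transcript_id="T-",
        gene_id="GM",
        gene_name="GM",
        contig="c1",
        strand="-",
        exons=[(30, 36), (40, 46)],
        cds=[(30, 36), (40, 46)],
        canonical_flag=True,
    )
    return {"contigs": {"c1": contig}, "plus": plus, "minus": minus}


@pytest.fixture()
def random_transcripts():
    """Factory for random synthetic transcripts with their contig sequences."""
    import numpy as np

    from spliceflank.junctions import TranscriptModel

    def make(n: int, seed: int = 0, micro_exons: bool = True):
        rng = np.random.default_rng(seed)
        transcripts = []
        contigs = {}
        for i in range(n):
            contig = f"rc{i}"
            n_ex = int(rng.integers(1, 7))
            cursor = int(rng.integers(0, 30))
            exons, cds = [], []
            for j in range(n_ex):
                lo = 1 if micro_exons else 3
                length = int(rng.integers(lo, 40))
                exons.append((cursor, cursor + length))
                cds.append((cursor, cursor + length))
                cursor += length + int(rng.integers(20, 60))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = "".join(rng.choice(list("ACGT"), size=cursor + 10))
            contigs[contig] = seq
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"rt{i}",
                    gene_id=f"rg{i}",
                    gene_name=f"rg{i}",
                    contig=contig,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                    canonical_flag=True,
                )
            )
        return contigs, transcripts

    return make
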