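"""End-to-end pipeline orchestration.

Stages (each restartable from its on-disk intermediates):

    simulate -> extract-junctions -> annotate -> signatures -> enrich
             -> evaluate-tools

All outputs are plain TSV/JSON written deterministically; a run manifest
records the seed, package version and input checksums, so identical config
plus identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx

from . import __version__
from .errors import SpliceflankError
from .junctions import (
    JunctionSite,
    SiteIndex,
    parse_gtf,
    read_sites_bed,
    select_canonical,
    sites_from_annotation,
    write_sites_bed,
)
from .enrichment import (
    conservation_summary,
    chisq_independence,
    gene_summary_frame,
    hypergeom_overlap,
    kruskal_wallis,
    loeuf_bin_table,
    low_loeuf_contingency,
    per_exon_gene_scores,
    rank_top_genes,
)
from .signatures import (
    background_composition,
    consequence_proportions,
    substitution_matrix,
    variant_site_composition,
)
from .simulate import SimulationConfig, simulate_all
from .tool_eval import (
    DEFAULT_THRESHOLDS,
    apply_thresholds,
    crosstab_for_label,
    roc_auc_for_tool,
)
from .variants import (
    AnnotatedJunctionVariant,
    VariantRecord,
    annotate_consequences,
    annotated_to_frame,
    assign_to_junctions,
    attach_labels,
    attach_scores,
    filter_population,
    read_variants,
    recurrence,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    out_dir: Path
    gtf: Path | None = None
    fasta: Path | None = None
    variant_tables: list[tuple[Path, str, str]] = field(default_factory=list)
    # (path, dialect, dataset)
    scores: Path | None = None
    labels: dict[str, Path] = field(default_factory=dict)
    loeuf: Path | None = None
    gene_sets: dict[str, Path] = field(default_factory=dict)
    conservation: Path | None = None
    af_cutoff: float = 0.001
    ranking_floor: float = 0.4
    top_m: int = 100
    seed: int = 0
    simulate: bool = False
    sim_config: SimulationConfig | None = None
    canonical_tag: str = "Ensembl_canonical"
    threshold_overrides: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.simulate:
            for path in [self.gtf, self.fasta] + [p for p, _, _ in self.variant_tables]:
                if path is None or not Path(path).exists():
                    raise SpliceflankError(f"input path missing: {path}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def load_conservation(path: Path) -> dict[tuple[str, int], float]:
    """BedGraph or 3-column TSV (contig, 0-based position, score)."""
    out = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 4:  # bedgraph: contig start end value
                contig, start, end, value = fields
                for pos in range(int(start), int(end)):
                    out[(contig, pos)] = float(value)
            elif len(fields) == 3:
                contig, pos, value = fields
                out[(contig, int(pos))] = float(value)
    return out


def annotated_from_frame(frame: pd.DataFrame) -> list[AnnotatedJunctionVariant]:
    """Rebuild annotated variants from the on-disk annotated.tsv intermediate."""
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    label_cols = [c for c in frame.columns if c.startswith("label_")]
    out = []
    by_key: dict[tuple, VariantRecord] = {}
    for row in frame.itertuples(index=False):
        key = (str(row.contig), int(row.pos) - 1, str(row.ref), str(row.alt))
        # the same SNV may occur in several datasets as distinct records
        cache_key = key + (str(row.dataset),)
        variant = by_key.get(cache_key)
        if variant is None:
            variant = VariantRecord(
                contig=key[0],
                position=key[1],
                ref=key[2],
                alt=key[3],
                dataset=str(row.dataset),
                af=None if pd.isna(row.af) else float(row.af),
                occurrence=int(row.occurrence),
                tissue=None if pd.isna(row.tissue) else str(row.tissue),
                scores={
                    c[len("score_"):]: float(getattr(row, c))
                    for c in score_cols
                    if not pd.isna(getattr(row, c))
                },
                labels={
                    c[len("label_"):]: str(getattr(row, c))
                    for c in label_cols
                    if not pd.isna(getattr(row, c))
                },
            )
            by_key[cache_key] = variant
        coding_ref, coding_alt = str(row.substitution).split(">")
        site = JunctionSite(
            contig=key[0],
            genomic_position=key[1],
            strand=str(row.strand),
            role=str(row.role),
            offset=int(row.offset),
            ref_base=coding_ref,
            exon_key="",
            gene_ids=(str(row.gene),),
        )
        out.append(
            AnnotatedJunctionVariant(
                variant=variant,
                site=site,
                coding_ref=coding_ref,
                coding_alt=coding_alt,
                consequence=str(row.consequence),
                gene_id=str(row.gene),
            )
        )
    return out


def stage_extract_junctions(
    gtf: Path, fasta, out_bed: Path, canonical_tag: str = "Ensembl_canonical"
) -> SiteIndex:
    transcripts = parse_gtf(str(gtf), canonical_tag=canonical_tag)
    index = sites_from_annotation(transcripts, fasta)
    write_sites_bed(index, str(out_bed))
    return index


def stage_annotate(
    config: RunConfig, site_index: SiteIndex, fasta, out_tsv: Path
) -> list[AnnotatedJunctionVariant]:
    transcripts = select_canonical(
        parse_gtf(str(config.gtf), canonical_tag=config.canonical_tag)
    )
    by_gene = {t.gene_id: t for t in transcripts}
    variants: list[VariantRecord] = []
    for path, dialect, dataset in config.variant_tables:
        variants.extend(read_variants(str(path), dialect, dataset=dataset))
    kept, removed = filter_population(variants, af_cutoff=config.af_cutoff)
    log.info("AF filter: kept %d, removed %d common records", len(kept), len(removed))
    if config.scores is not None:
        attach_scores(kept, pd.read_csv(config.scores, sep="\t", dtype={"chrom": str}))
    for name, path in config.labels.items():
        attach_labels(kept, pd.read_csv(path, sep="\t", dtype={"chrom": str}), name)
    annotated = assign_to_junctions(kept, site_index)
    annotated = annotate_consequences(annotated, by_gene, fasta)
    frame = annotated_to_frame(annotated)
    frame = frame.sort_values(["contig", "pos", "ref", "alt", "role", "offset"])
    # shortest round-trip float repr: scores must reload exactly, or restarted
    # stages could flip threshold calls
    frame.to_csv(out_tsv, sep="\t", index=False)
    return annotated


def stage_signatures(
    annotated: list[AnnotatedJunctionVariant], site_index: SiteIndex, outdir: Path
) -> dict:
    background = background_composition(site_index)
    cosmic = [a for a in annotated if a.variant.dataset == "cosmic"]
    site_comp = variant_site_composition(cosmic)
    matrix = substitution_matrix(cosmic, split_by_consequence=True)
    proportions = consequence_proportions(cosmic, site_index)
    _write_tsv(background.counts, outdir / "composition_background.tsv", index=True)
    _write_tsv(site_comp.counts, outdir / "composition_variant_sites.tsv", index=True)
    _write_tsv(matrix.combined, outdir / "signature.tsv", index=True)
    _write_tsv(matrix.silent, outdir / "signature_silent.tsv", index=True)
    _write_tsv(matrix.missense, outdir / "signature_missense.tsv", index=True)
    _write_tsv(proportions, outdir / "proportions.tsv", index=True)
    summary = {
        "background_fractions": background.fractions.round(6).to_dict(),
        "variant_site_fractions": site_comp.fractions.round(6).to_dict(),
        "proportions": proportions.round(4).to_dict(),
    }
    with open(outdir / "signatures_summary.json", "w") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
    return summary


def stage_enrich(
    config: RunConfig,
    annotated: list[AnnotatedJunctionVariant],
    gene_exon_counts: dict[str, int],
    outdir: Path,
) -> dict:
    loeuf = {}
    if config.loeuf is not None:
        table = pd.read_csv(config.loeuf, sep="\t")
        loeuf = dict(zip(table["gene"], table["loeuf"].astype(float)))
    gene_sets = {
        name: set(Path(path).read_text().split())
        for name, path in config.gene_sets.items()
    }
    universe = set(gene_exon_counts)
    gene_sets = {n: members & universe for n, members in gene_sets.items()}

    by_dataset: dict[str, list[AnnotatedJunctionVariant]] = {}
    for av in annotated:
        by_dataset.setdefault(av.variant.dataset, []).append(av)

    summaries = {
        ds: per_exon_gene_scores(avs, gene_exon_counts, loeuf=loeuf, gene_sets=gene_sets)
        for ds, avs in by_dataset.items()
    }
    ranked = {
        ds: [
            s.gene_id
            for s in rank_top_genes(
                sums, m=config.top_m, floor=config.ranking_floor
            )
        ]
        for ds, sums in summaries.items()
    }
    for ds, sums in summaries.items():
        _write_tsv(gene_summary_frame(sums), outdir / f"gene_summary_{ds}.tsv")

    results = {}
    cosmic = by_dataset.get("cosmic", [])
    rec = recurrence(cosmic)
    recurrent_genes = set()
    gene_of_variant: dict[tuple, set[str]] = {}
    for av in cosmic:
        gene_of_variant.setdefault(av.key, set()).update(av.site.gene_ids)
    for key, count in rec.counts.items():
        if count >= 2:
            recurrent_genes.update(gene_of_variant.get(key, ()))
    enr_rows = []
    for name, members in sorted(gene_sets.items()):
        if not members:
            continue
        res = hypergeom_overlap(recurrent_genes, members, universe, set_name=name)
        enr_rows.append(dataclasses.asdict(res))
    if enr_rows:
        _write_tsv(pd.DataFrame(enr_rows), outdir / "enrichment.tsv")
    results["recurrence"] = {
        "n_unique": rec.n_unique,
        "fraction_ge2": rec.fraction_at_least(2),
        "fraction_ge5": rec.fraction_at_least(5),
        "strata": rec.strata(),
    }

    bins = loeuf_bin_table(ranked, loeuf, m=config.top_m)
    _write_tsv(bins, outdir / "loeuf_bins.tsv", index=True)
    results["loeuf_bins"] = bins.to_dict()
    if "cosmic" in bins.index and any(d.startswith("gnomad") for d in bins.index):
        other = [d for d in bins.index if d.startswith("gnomad")][0]
        table = low_loeuf_contingency(bins.loc[[ "cosmic", other]], boundary="0.66")
        stat, df, p = chisq_independence(table.T)
        results["low_loeuf_chisq"] = {"statistic": stat, "df": df, "p": p,
                                      "datasets": ["cosmic", other]}

    tissues: dict[str, list[float]] = {}
    for av in cosmic:
        if av.variant.tissue:
            tissues.setdefault(av.variant.tissue, []).append(av.variant.occurrence)
    if len(tissues) >= 2:
        h, df, p = kruskal_wallis(tissues)
        results["tissue_kruskal"] = {"H": h, "df": df, "p": p}

    if config.conservation is not None:
        scores = load_conservation(Path(config.conservation))
        cons = conservation_summary(annotated, scores)
        _write_tsv(cons, outdir / "conservation_summary.tsv")
        results["conservation"] = cons.to_dict(orient="records")

    with open(outdir / "enrichment_summary.json", "w") as handle:
        json.dump(results, handle, indent=1, sort_keys=True, default=float)
    return results


def stage_evaluate_tools(
    annotated: list[AnnotatedJunctionVariant],
    outdir: Path,
    threshold_overrides: dict[str, float] | None = None,
) -> dict:
    cosmic = [a for a in annotated if a.variant.dataset == "cosmic"]
    eval_rows = []
    results: dict = {"auc": {}}
    roc_frames = []
    for tool, spec in DEFAULT_THRESHOLDS.items():
        if threshold_overrides and tool in threshold_overrides:
            spec = dataclasses.replace(spec, threshold=threshold_overrides[tool])
        _, summary = apply_thresholds(cosmic, tool, spec)
        summary = summary.reset_index()
        summary.insert(0, "tool", tool)
        eval_rows.append(summary)
        try:
            res = roc_auc_for_tool(annotated, tool)
        except SpliceflankError:
            continue
        results["auc"][tool] = {
            "auc": res.auc,
            "n_scored": res.n_scored,
            "n_unscored": res.n_unscored,
        }
        roc_frames.append(
            pd.DataFrame({"tool": tool, "fpr": res.fpr, "tpr": res.tpr})
        )
    _write_tsv(pd.concat(eval_rows, ignore_index=True), outdir / "eval.tsv")
    if roc_frames:
        _write_tsv(pd.concat(roc_frames, ignore_index=True), outdir / "roc_points.tsv")
    for label_name in ("clinvar", "splicevardb"):
        if any(label_name in a.variant.labels for a in annotated):
            crosstab = crosstab_for_label(annotated, label_name)
            _write_tsv(crosstab, outdir / f"crosstab_{label_name}.tsv")
            results[f"crosstab_{label_name}"] = crosstab.to_dict(orient="records")
    with open(outdir / "tool_eval_summary.json", "w") as handle:
        json.dump(results, handle, indent=1, sort_keys=True, default=float)
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the collected summary dict."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = config.sim_config or SimulationConfig(seed=config.seed)
        inputs = outdir / "inputs"
        artifacts = simulate_all(sim, inputs)
        paths = artifacts["paths"]
        config.gtf = paths["gtf"]
        config.fasta = paths["fasta"]
        config.variant_tables = [
            (paths["cosmic_tsv"], "cosmic_tsv", "cosmic"),
            (paths["gnomad_tsv"], "gnomad_tsv", "gnomad"),
        ]
        config.scores = paths["scores"]
        config.labels = {
            "splice_altering": paths["labels_splice_altering"],
            "clinvar": paths["labels_clinvar"],
            "splicevardb": paths["labels_splicevardb"],
        }
        config.loeuf = paths["loeuf"]
        config.gene_sets = {
            name: paths[name] for name in ("TSG", "oncogene", "CGC") if name in paths
        }
        config.conservation = paths["conservation"]

    fasta = pyfaidx.Fasta(str(config.fasta))
    site_index = stage_extract_junctions(
        config.gtf, fasta, outdir / "sites.bed", canonical_tag=config.canonical_tag
    )
    annotated = stage_annotate(config, site_index, fasta, outdir / "annotated.tsv")
    signatures_summary = stage_signatures(annotated, site_index, outdir)
    canonical = select_canonical(
        parse_gtf(str(config.gtf), canonical_tag=config.canonical_tag)
    )
    from .junctions import trim_to_cds

    gene_exon_counts = {t.gene_id: len(trim_to_cds(t)) for t in canonical}
    enrich_summary = stage_enrich(config, annotated, gene_exon_counts, outdir)
    eval_summary = stage_evaluate_tools(
        annotated, outdir, threshold_overrides=config.threshold_overrides
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "af_cutoff": config.af_cutoff,
        "ranking_floor": config.ranking_floor,
        "top_m": config.top_m,
        "inputs": {
            Path(p).name: _sha256(Path(p))
            for p in [config.gtf, config.fasta]
            + [p for p, _, _ in config.variant_tables]
            if p is not None
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return {
        "signatures": signatures_summary,
        "enrichment": enrich_summary,
        "tool_eval": eval_summary,
        "n_annotated": len(annotated),
    }


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML key-value file.

    Recognised keys mirror the dataclass fields; ``variant_tables`` is a list
    of ``{path, dialect, dataset}`` mappings, ``gene_sets`` / ``labels`` are
    name-to-path mappings, and ``sim`` holds SimulationConfig overrides
    (``simulate: true`` turns generation on).  Relative paths are resolved
    against the config file's directory.
    """
    import yaml

    path = Path(path)
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    config = RunConfig(out_dir=resolve(raw.get("out_dir", "out")))
    for key in ("af_cutoff", "ranking_floor", "top_m", "seed", "simulate",
                "canonical_tag"):
        if key in raw:
            setattr(config, key, raw[key])
    for key in ("gtf", "fasta", "scores", "loeuf", "conservation"):
        if raw.get(key):
            setattr(config, key, resolve(raw[key]))
    for entry in raw.get("variant_tables", []):
        config.variant_tables.append(
            (resolve(entry["path"]), entry["dialect"], entry["dataset"])
        )
    config.gene_sets = {k: resolve(v) for k, v in raw.get("gene_sets", {}).items()}
    config.labels = {k: resolve(v) for k, v in raw.get("labels", {}).items()}
    config.threshold_overrides = dict(raw.get("threshold_overrides", {}))
    if raw.get("sim"):
        sim_kwargs = dict(raw["sim"])
        sim_kwargs.setdefault("seed", config.seed)
        config.sim_config = SimulationConfig(**sim_kwargs)
    return config
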