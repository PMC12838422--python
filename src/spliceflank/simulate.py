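"""Synthetic genome / annotation / variant generator with planted structure.

Generates a self-consistent toy locus set: a contig of protein-coding genes
with GT..AG introns, a GENCODE-dialect GTF, COSMIC- and gnomAD-style variant
tables, per-tool splice-impact scores, constraint (LOEUF) and conservation
tables, gene-set lists and clinical-category labels — all with configurable,
recoverable planted parameters, plus a machine-readable ground-truth file.

Planted structure mirrors the patterns the analysis is built to measure:

* background exonic consensus at the six flank positions (defaults: G 80% at
  d1, A 64% at d2, G 49% at a1, U/T 37% at a2);
* a per-position 12-type substitution spectrum for junction variants whose
  reference-base marginals give the variant-site composition (default 87% G
  among d1 variant sites, with G>T and G>A dominating d1/a1);
* a per-position missense/silent mixture (default 78/22 at d1, 86/14 at a1).

Because the consequence of an SNV is dictated by its codon context, the
mixture is planted by *selecting among candidate (site, alt) pairs whose true
translated consequence matches the sampled target* — consequences are never
fabricated.  The substitution type is sampled before the site, so spectrum
and mixture are both recovered.

One RNG stream per output concern, all derived from the single seed, so
adding a dataset never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import CapacityError, ConfigError, LayoutError
from .junctions import BASES, POSITIONS, complement, revcomp
from .variants import SUBSTITUTIONS, VariantRecord, translate_codon

_TOL = 1e-9


def _check_probs(name: str, probs: Mapping[str, float]) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > _TOL:
        raise ConfigError(f"{name}: probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ConfigError(f"{name}: negative probability")


#: Background base composition of the exonic flank positions.
DEFAULT_CONSENSUS: dict[str, dict[str, float]] = {
    "d1": {"G": 0.80, "A": 0.08, "C": 0.06, "T": 0.06},
    "d2": {"A": 0.64, "G": 0.14, "C": 0.12, "T": 0.10},
    "d3": {"C": 0.35, "A": 0.34, "G": 0.16, "T": 0.15},
    "a1": {"G": 0.49, "A": 0.21, "C": 0.17, "T": 0.13},
    "a2": {"T": 0.37, "C": 0.25, "G": 0.21, "A": 0.17},
    "a3": {"G": 0.30, "C": 0.28, "A": 0.22, "T": 0.20},
}


def _sub_table(entries: Mapping[str, float]) -> dict[str, float]:
    table = {s: 0.0 for s in SUBSTITUTIONS}
    table.update(entries)
    return table


#: Planted 12-type substitution spectrum per position (coding strand).  The
#: reference-base marginals define the variant-site composition; the d1/a1
#: tables are dominated by G>T and G>A.
DEFAULT_ENRICHMENT: dict[str, dict[str, float]] = {
    "d1": _sub_table({
        "G>T": 0.400, "G>A": 0.396, "G>C": 0.074,
        "A>G": 0.030, "A>C": 0.010, "A>T": 0.010,
        "C>T": 0.028, "C>A": 0.006, "C>G": 0.006,
        "T>C": 0.024, "T>A": 0.008, "T>G": 0.008,
    }),
    "d2": _sub_table({
        "A>G": 0.197, "A>C": 0.092, "A>T": 0.091,
        "C>T": 0.233, "C>A": 0.034, "C>G": 0.033,
        "G>A": 0.102, "G>T": 0.034, "G>C": 0.034,
        "T>C": 0.090, "T>A": 0.030, "T>G": 0.030,
    }),
    "d3": _sub_table({
        "C>T": 0.229, "C>A": 0.061, "C>G": 0.060,
        "G>A": 0.150, "G>T": 0.050, "G>C": 0.050,
        "A>G": 0.150, "A>C": 0.050, "A>T": 0.050,
        "T>C": 0.090, "T>A": 0.030, "T>G": 0.030,
    }),
    "a1": _sub_table({
        "G>A": 0.408, "G>T": 0.217, "G>C": 0.065,
        "A>G": 0.072, "A>C": 0.024, "A>T": 0.024,
        "C>T": 0.060, "C>A": 0.020, "C>G": 0.020,
        "T>C": 0.054, "T>A": 0.018, "T>G": 0.018,
    }),
    "a2": _sub_table({
        "C>T": 0.230, "C>A": 0.060, "C>G": 0.060,
        "G>A": 0.180, "G>T": 0.060, "G>C": 0.060,
        "T>C": 0.120, "T>A": 0.040, "T>G": 0.040,
        "A>G": 0.090, "A>C": 0.030, "A>T": 0.030,
    }),
    "a3": _sub_table({
        "C>T": 0.248, "C>A": 0.041, "C>G": 0.041,
        "G>A": 0.192, "G>T": 0.064, "G>C": 0.064,
        "A>G": 0.120, "A>C": 0.040, "A>T": 0.040,
        "T>C": 0.090, "T>A": 0.030, "T>G": 0.030,
    }),
}

#: Missense fraction among silent+missense junction variants, per position.
DEFAULT_CONSEQUENCE_MIX: dict[str, float] = {
    "d1": 0.78, "d2": 0.70, "d3": 0.72, "a1": 0.861, "a2": 0.74, "a3": 0.70,
}

#: Relative share of junction variants per position (proportional to the
#: unique-SNV tallies reported for COSMIC v98: 30738/19008/19642 at d1-d3,
#: 20863/18083/20317 at a1-a3).
DEFAULT_POSITION_WEIGHTS: dict[str, float] = {
    "d1": 30738, "d2": 19008, "d3": 19642, "a1": 20863, "a2": 18083, "a3": 20317,
}

DEFAULT_TISSUES: tuple[tuple[str, float], ...] = (
    ("skin", 0.20), ("lung", 0.18), ("endometrium", 0.14), ("breast", 0.10),
    ("large_intestine", 0.10), ("liver", 0.08), ("kidney", 0.08), ("stomach", 0.12),
)

DEFAULT_CLINVAR_PROBS: dict[str, float] = {
    "pathogenic": 0.100,
    "likely_pathogenic": 0.064,
    "uncertain_significance": 0.771,
    "likely_benign": 0.025,
    "benign": 0.040,
}

DEFAULT_SPLICEVARDB_PROBS: dict[str, float] = {
    "splice_altering": 0.47,
    "low_frequency": 0.43,
    "normal": 0.10,
}


@dataclass
class AFModel:
    """Log10-normal mixture of allele frequencies straddling the 0.1% cutoff."""

    frac_missing: float = 0.10
    components: tuple[tuple[float, float, float], ...] = (
        (0.75, -4.0, 0.6),   # very rare: median 1e-4
        (0.25, -2.3, 0.5),   # around and above the 0.1% cutoff: median 5e-3
    )

    def sample(self, rng: np.random.Generator) -> float | None:
        if rng.random() < self.frac_missing:
            return None
        weights = np.array([w for w, _, _ in self.components])
        idx = rng.choice(len(self.components), p=weights / weights.sum())
        _, mu, sd = self.components[idx]
        return float(np.clip(10 ** rng.normal(mu, sd), 1e-6, 0.5))


@dataclass
class RecurrenceModel:
    """Zero-truncated geometric occurrence counts: P(occ >= 2) = 1 - q."""

    q: float = 0.88
    q_hot: float | None = 0.72  # cancer variants in hot genes recur more

    def sample(self, rng: np.random.Generator, hot: bool) -> int:
        q = self.q_hot if (hot and self.q_hot is not None) else self.q
        return int(rng.geometric(q))


@dataclass
class ScoreModel:
    """Score distribution of one tool conditional on the latent altering flag."""

    kind: str = "beta"  # beta | normal
    altering: tuple[float, float] = (8.0, 2.0)
    neutral: tuple[float, float] = (2.0, 8.0)
    lo: float = 0.0
    hi: float = 1.0
    coverage: float = 1.0

    def sample(self, rng: np.random.Generator, altering: bool) -> float | None:
        if self.coverage < 1.0 and rng.random() >= self.coverage:
            return None
        a, b = self.altering if altering else self.neutral
        if self.kind == "beta":
            return float(self.lo + (self.hi - self.lo) * rng.beta(a, b))
        if self.kind == "normal":
            return float(rng.normal(a, b))
        raise ConfigError(f"unknown score model kind {self.kind!r}")


def default_score_models() -> dict[str, ScoreModel]:
    return {
        "spliceai": ScoreModel(coverage=0.955),
        "pangolin": ScoreModel(),
        "maxentscan_diff": ScoreModel(
            kind="normal", altering=(4.5, 2.5), neutral=(-1.0, 2.0)
        ),
        # inverted scale: low alternate-allele score = high disruption potential
        "maxentscan_alt": ScoreModel(altering=(2.0, 8.0), neutral=(8.0, 2.0), lo=0.0, hi=12.0),
        "cadd": ScoreModel(lo=0.0, hi=50.0, coverage=0.775),
        "spip": ScoreModel(),
        "absplice": ScoreModel(coverage=0.90),
    }


@dataclass
class LoeufModel:
    """Mixture over the four constraint bins, enriched for low bins in hot genes."""

    hot_bin_probs: tuple[float, float, float, float] = (0.38, 0.27, 0.20, 0.15)
    cold_bin_probs: tuple[float, float, float, float] = (0.03, 0.07, 0.15, 0.75)
    upper: float = 2.0
    missing_rate: float = 0.03

    _EDGES = (0.0, 0.33, 0.66, 1.0)

    def sample(self, rng: np.random.Generator, hot: bool) -> float | None:
        if rng.random() < self.missing_rate:
            return None
        probs = self.hot_bin_probs if hot else self.cold_bin_probs
        b = int(rng.choice(4, p=np.asarray(probs) / sum(probs)))
        lo = self._EDGES[b]
        hi = self._EDGES[b + 1] if b < 3 else self.upper
        return float(rng.uniform(lo, hi))


@dataclass
class SimulationConfig:
    """All planted parameters of one synthetic study."""

    seed: int = 0
    n_genes: int = 500
    exons_per_gene_range: tuple[int, int] = (8, 16)
    exon_length_range: tuple[int, int] = (60, 150)   # coding part, >= 9
    intron_length_range: tuple[int, int] = (60, 240)  # >= 20
    frac_minus_strand: float = 0.5
    utr_fraction: float = 0.5
    utr_length_range: tuple[int, int] = (6, 30)
    intergenic_gap: int = 60
    contig_length: int | None = None  # None = sized to fit
    contig_name: str = "chrS"
    noncanonical_fraction: float = 0.25

    exonic_consensus: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(DEFAULT_CONSENSUS[p]) for p in POSITIONS}
    )
    n_variants_per_dataset: dict[str, int] = field(
        default_factory=lambda: {"cosmic": 12000, "gnomad": 8000}
    )
    frac_junction: float = 0.85
    position_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_WEIGHTS)
    )
    substitution_enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(DEFAULT_ENRICHMENT[p]) for p in POSITIONS}
    )
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    af_model: AFModel = field(default_factory=AFModel)
    recurrence_model: RecurrenceModel = field(default_factory=RecurrenceModel)
    hot_gene_fraction: float = 0.2
    hot_gene_weight: float = 4.0
    score_models: dict[str, ScoreModel] = field(default_factory=default_score_models)
    p_altering: dict[str, float] = field(
        default_factory=lambda: {"cosmic": 0.55, "gnomad": 0.15, "background": 0.05}
    )
    loeuf_model: LoeufModel = field(default_factory=LoeufModel)
    tissue_labels: tuple[tuple[str, float], ...] = DEFAULT_TISSUES
    gene_set_fractions: dict[str, float] = field(
        default_factory=lambda: {"TSG": 0.05, "oncogene": 0.05, "CGC": 0.10}
    )
    gene_set_hot_weight: float = 6.0
    clinvar_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINVAR_PROBS)
    )
    clinvar_coverage: float = 0.055
    splicevardb_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPLICEVARDB_PROBS)
    )
    splicevardb_coverage: float = 0.009
    validated_label_fraction: float = 0.12

    def validate(self) -> None:
        if self.exon_length_range[0] < 9:
            raise ConfigError("minimum exon length must be >= 9")
        if self.intron_length_range[0] < 20:
            raise ConfigError("minimum intron length must be >= 20")
        if not 0.0 <= self.frac_minus_strand <= 1.0:
            raise ConfigError("frac_minus_strand must be in [0,1]")
        for p in POSITIONS:
            _check_probs(f"exonic_consensus[{p}]", self.exonic_consensus[p])
            _check_probs(
                f"substitution_enrichment[{p}]", self.substitution_enrichment[p]
            )
            if not 0.0 <= self.consequence_mix[p] <= 1.0:
                raise ConfigError(f"consequence_mix[{p}] outside [0,1]")
        _check_probs("clinvar_probs", self.clinvar_probs)
        _check_probs("splicevardb_probs", self.splicevardb_probs)

    def rng(self, stream: str) -> np.random.Generator:
        streams = (
            "genes", "genome", "variants_cosmic", "variants_gnomad",
            "scores", "labels", "conservation", "loeuf", "genesets",
        )
        return np.random.default_rng([self.seed, streams.index(stream)])


@dataclass
class PlantedSite:
    """Ground-truth junction flank position with its codon context."""

    gene_index: int
    gene_id: str
    contig: str
    genomic_position: int
    strand: str
    role: str
    offset: int
    ref_base: str  # coding strand
    codon: str     # coding strand
    pos_in_codon: int
    cds_index: int
    hot: bool
    alt_consequences: dict[str, str] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return ("d" if self.role == "donor" else "a") + str(self.offset)


@dataclass
class GenePlan:
    gene_index: int
    gene_id: str
    gene_name: str
    transcript_id: str
    contig: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]     # genomic, includes UTR on terminal exons
    cds: list[tuple[int, int]]       # genomic
    exon_count: int
    hot: bool
    cds_genomic_positions: list[int]  # coding order
    sites: list[PlantedSite] = field(default_factory=list)


@dataclass
class Genome:
    """Contig sequences plus the generating gene plans (the ground truth)."""

    contigs: dict[str, str]
    genes: list[GenePlan]

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def keys(self):
        return self.contigs.keys()

    def junction_sites(self) -> list[PlantedSite]:
        return [s for g in self.genes for s in g.sites]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for name in sorted(self.contigs):
                handle.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), 60):
                    handle.write(seq[i : i + 60] + "\n")


def _sample_base(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    bases = list(BASES)
    p = np.array([probs.get(b, 0.0) for b in bases])
    return bases[int(rng.choice(4, p=p / p.sum()))]


def _plan_gene_local(config: SimulationConfig, rng: np.random.Generator):
    """Coding-strand local layout: sequence, exon/CDS local intervals, flank map."""
    elo, ehi = config.exons_per_gene_range
    n_ex = int(rng.integers(elo, ehi + 1))
    cds_lens = rng.integers(
        config.exon_length_range[0], config.exon_length_range[1] + 1, n_ex
    ).tolist()
    total = sum(cds_lens)
    cds_lens[-1] += (3 - total % 3) % 3  # CDS length divisible by 3
    introns = rng.integers(
        config.intron_length_range[0], config.intron_length_range[1] + 1, max(n_ex - 1, 0)
    ).tolist()
    if rng.random() < config.utr_fraction:
        utr5 = int(rng.integers(*config.utr_length_range))
        utr3 = int(rng.integers(*config.utr_length_range))
    else:
        utr5 = utr3 = 0

    exon_local: list[tuple[int, int]] = []
    cds_local: list[tuple[int, int]] = []
    cursor = 0
    for i in range(n_ex):
        exon_start = cursor
        if i == 0:
            cursor += utr5
        cds_start = cursor
        cursor += cds_lens[i]
        cds_end = cursor
        if i == n_ex - 1:
            cursor += utr3
        exon_local.append((exon_start, cursor))
        cds_local.append((cds_start, cds_end))
        if i < n_ex - 1:
            intron_start = cursor
            cursor += introns[i]
            exon_local[-1] = (exon_start, intron_start)
    length = cursor

    seq = rng.choice(list("ACGT"), size=length).tolist()
    # canonical intron dinucleotides on the coding strand
    for i in range(n_ex - 1):
        intron_start = exon_local[i][1]
        intron_end = exon_local[i + 1][0]
        seq[intron_start], seq[intron_start + 1] = "G", "T"
        seq[intron_end - 2], seq[intron_end - 1] = "A", "G"

    # local CDS positions in coding order + flank planting
    cds_positions: list[int] = []
    for s, e in cds_local:
        cds_positions.extend(range(s, e))
    flank_map: list[tuple[int, str, int]] = []  # (cds_index, role, offset)
    offset_cursor = 0
    for i, ln in enumerate(cds_lens):
        start_idx = offset_cursor
        end_idx = offset_cursor + ln
        if i < n_ex - 1:  # donor side of this exon
            for k in (1, 2, 3):
                if k <= ln:
                    flank_map.append((end_idx - k, "donor", k))
        if i > 0:  # acceptor side
            for k in (1, 2, 3):
                if k <= ln:
                    flank_map.append((start_idx + (k - 1), "acceptor", k))
        offset_cursor = end_idx
    for cds_index, role, offset in flank_map:
        label = ("d" if role == "donor" else "a") + str(offset)
        base = _sample_base(rng, config.exonic_consensus[label])
        seq[cds_positions[cds_index]] = base

    return {
        "seq": "".join(seq),
        "exon_local": exon_local,
        "cds_local": cds_local,
        "cds_positions": cds_positions,
        "flank_map": flank_map,
        "n_ex": n_ex,
        "length": length,
    }


def generate_genome(config: SimulationConfig) -> Genome:
    """Build the contig and all gene plans, deterministic under the seed."""
    config.validate()
    gene_rng = config.rng("genes")
    rng = config.rng("genome")
    hot_flags = gene_rng.random(config.n_genes) < config.hot_gene_fraction
    minus_flags = gene_rng.random(config.n_genes) < config.frac_minus_strand

    pieces: list[str] = []
    genes: list[GenePlan] = []
    offset = config.intergenic_gap
    pad = "".join(rng.choice(list("ACGT"), size=config.intergenic_gap))
    pieces.append(pad)
    for g in range(config.n_genes):
        local = _plan_gene_local(config, rng)
        strand = "-" if minus_flags[g] else "+"
        length = local["length"]
        seq = local["seq"] if strand == "+" else revcomp(local["seq"])

        def to_genomic_interval(iv: tuple[int, int]) -> tuple[int, int]:
            s, e = iv
            if strand == "+":
                return (offset + s, offset + e)
            return (offset + length - e, offset + length - s)

        def to_genomic_pos(p: int) -> int:
            return offset + p if strand == "+" else offset + length - 1 - p

        exons = sorted(to_genomic_interval(iv) for iv in local["exon_local"])
        cds = sorted(to_genomic_interval(iv) for iv in local["cds_local"])
        gene_id = f"G{g:05d}"
        plan = GenePlan(
            gene_index=g,
            gene_id=gene_id,
            gene_name=f"SYN{g:05d}",
            transcript_id=f"T{g:05d}.1",
            contig=config.contig_name,
            strand=strand,
            span=(offset, offset + length),
            exons=exons,
            cds=cds,
            exon_count=local["n_ex"],
            hot=bool(hot_flags[g]),
            cds_genomic_positions=[to_genomic_pos(p) for p in local["cds_positions"]],
        )
        cds_seq = "".join(local["seq"][p] for p in local["cds_positions"])
        for cds_index, role, offset_k in local["flank_map"]:
            codon_start = 3 * (cds_index // 3)
            codon = cds_seq[codon_start : codon_start + 3]
            pos_in_codon = cds_index % 3
            ref_base = cds_seq[cds_index]
            site = PlantedSite(
                gene_index=g,
                gene_id=gene_id,
                contig=config.contig_name,
                genomic_position=to_genomic_pos(local["cds_positions"][cds_index]),
                strand=strand,
                role=role,
                offset=offset_k,
                ref_base=ref_base,
                codon=codon,
                pos_in_codon=pos_in_codon,
                cds_index=cds_index,
                hot=bool(hot_flags[g]),
            )
            ref_aa = translate_codon(codon)
            for alt in BASES:
                if alt == ref_base:
                    continue
                alt_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
                alt_aa = translate_codon(alt_codon)
                if ref_aa == "*":
                    cons = "other"
                elif alt_aa == "*":
                    cons = "nonsense"
                elif alt_aa == ref_aa:
                    cons = "silent"
                else:
                    cons = "missense"
                site.alt_consequences[alt] = cons
            plan.sites.append(site)
        genes.append(plan)
        pieces.append(seq)
        gap = "".join(rng.choice(list("ACGT"), size=config.intergenic_gap))
        pieces.append(gap)
        offset += length + config.intergenic_gap

    contig = "".join(pieces)
    if config.contig_length is not None:
        if len(contig) > config.contig_length:
            raise LayoutError(
                f"gene layout needs {len(contig)} bp but contig_length is "
                f"{config.contig_length}"
            )
        extra = config.contig_length - len(contig)
        contig += "".join(rng.choice(list("ACGT"), size=extra))
    return Genome(contigs={config.contig_name: contig}, genes=genes)


def gtf_lines(config: SimulationConfig, genome: Genome) -> list[str]:
    """GENCODE-dialect GTF records (1-based inclusive) for all genes.

    One canonical tagged transcript per gene; a configurable fraction of genes
    also gets a shorter untagged isoform so canonical selection is exercised.
    """
    rng = config.rng("genes")
    rng.random(config.n_genes)  # skip hot flags
    rng.random(config.n_genes)  # skip strand flags
    extra_flags = rng.random(config.n_genes) < config.noncanonical_fraction
    lines = []
    for plan in genome.genes:
        s, e = plan.span
        attrs_gene = (
            f'gene_id "{plan.gene_id}"; gene_name "{plan.gene_name}"; '
            f'gene_type "protein_coding";'
        )
        lines.append(
            f"{plan.contig}\tsim\tgene\t{s + 1}\t{e}\t.\t{plan.strand}\t.\t{attrs_gene}"
        )

        def transcript_block(tid: str, exons, cds, tagged: bool):
            tag = ' tag "Ensembl_canonical";' if tagged else ""
            base = (
                f'gene_id "{plan.gene_id}"; gene_name "{plan.gene_name}"; '
                f'transcript_id "{tid}"; transcript_type "protein_coding";{tag}'
            )
            t_start = min(x[0] for x in exons)
            t_end = max(x[1] for x in exons)
            out = [
                f"{plan.contig}\tsim\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                f"{plan.strand}\t.\t{base}"
            ]
            for xs, xe in exons:
                out.append(
                    f"{plan.contig}\tsim\texon\t{xs + 1}\t{xe}\t.\t{plan.strand}\t.\t{base}"
                )
            for cs, ce in cds:
                out.append(
                    f"{plan.contig}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{plan.strand}\t.\t{base}"
                )
            return out

        lines.extend(
            transcript_block(plan.transcript_id, plan.exons, plan.cds, tagged=True)
        )
        if extra_flags[plan.gene_index] and len(plan.exons) > 2:
            # shorter isoform: drop the genomically-last exon
            lines.extend(
                transcript_block(
                    plan.transcript_id.replace(".1", ".2"),
                    plan.exons[:-1],
                    [iv for iv in plan.cds if iv[1] <= plan.exons[-2][1]],
                    tagged=False,
                )
            )
    return lines


def generate_annotation(
    config: SimulationConfig, genome: Genome, path: str | Path
) -> Path:
    path = Path(path)
    path.write_text("\n".join(gtf_lines(config, genome)) + "\n")
    return path


class _SitePools:
    """Sampling pools of unused (site, alt) slots keyed by label/ref/alt/consequence."""

    def __init__(self, sites: Sequence[PlantedSite], rng: np.random.Generator):
        self.rng = rng
        self.sites = list(sites)
        self.used_sites: set[int] = set()
        self.used_slots: set[tuple[int, str]] = set()
        self.fresh: dict[tuple, dict[str, list[int]]] = {}
        for idx, site in enumerate(self.sites):
            for alt, cons in site.alt_consequences.items():
                key = (site.label, site.ref_base, alt, cons)
                branch = "hot" if site.hot else "cold"
                self.fresh.setdefault(
                    key, {"hot": [], "cold": [], "spent": []}
                )[branch].append(idx)

    def _pop_fresh(self, key: tuple, hot_weight: float) -> int | None:
        """A never-used site matching the key; stale entries move to 'spent'."""
        pools = self.fresh.get(key)
        if not pools:
            return None
        while True:
            nh, nc = len(pools["hot"]), len(pools["cold"])
            if nh == 0 and nc == 0:
                return None
            p_hot = hot_weight * nh / (hot_weight * nh + nc) if nh else 0.0
            branch = pools["hot"] if self.rng.random() < p_hot else pools["cold"]
            if not branch:
                branch = pools["hot"] if branch is pools["cold"] else pools["cold"]
            j = int(self.rng.integers(len(branch)))
            branch[j], branch[-1] = branch[-1], branch[j]
            idx = branch.pop()
            if idx not in self.used_sites:
                return idx
            # site consumed through another alt: its slot here is still free
            pools["spent"].append(idx)

    def _pop_spent(self, key: tuple, alt: str) -> int | None:
        """An already-used site whose (site, alt) slot is still free."""
        pools = self.fresh.get(key)
        if not pools:
            return None
        spent = pools["spent"]
        while spent:
            j = int(self.rng.integers(len(spent)))
            spent[j], spent[-1] = spent[-1], spent[j]
            idx = spent.pop()
            if (idx, alt) not in self.used_slots:
                return idx
        return None

    def _claim(self, idx: int, alt: str) -> tuple[int, str, str]:
        self.used_sites.add(idx)
        self.used_slots.add((idx, alt))
        return idx, alt, self.sites[idx].alt_consequences[alt]

    def take(
        self, label: str, ref: str, alt: str, cons: str, hot_weight: float
    ) -> tuple[int, str, str] | None:
        """Return (site index, alt, actual consequence) or None if exhausted.

        Preference order keeps the planted spectrum and consequence mixture as
        faithful as the genome allows: a fresh site realising the exact target,
        then an already-used site realising it (costs only site uniqueness),
        then relaxing the consequence (nonsense/other before the opposite
        class, so the silent/missense ratio is disturbed last), then any free
        slot with the right reference base.
        """
        site_idx = self._pop_fresh((label, ref, alt, cons), hot_weight)
        if site_idx is not None:
            return self._claim(site_idx, alt)
        site_idx = self._pop_spent((label, ref, alt, cons), alt)
        if site_idx is not None:
            return self._claim(site_idx, alt)
        relax = ["nonsense", "other"] + (
            ["silent"] if cons == "missense" else ["missense"]
        )
        for other in relax:
            if other == cons:
                continue
            key = (label, ref, alt, other)
            site_idx = self._pop_fresh(key, hot_weight)
            if site_idx is None:
                site_idx = self._pop_spent(key, alt)
            if site_idx is not None:
                return self._claim(site_idx, alt)
        # the (ref, alt) substitution is exhausted at this label: emit nothing
        # rather than distort the planted spectrum
        return None


@dataclass
class GroundTruth:
    """Everything the generator planted, for round-trip and recovery tests."""

    sites: list[dict]
    variants: dict[str, list[dict]]
    genes: dict[str, dict]
    planted: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


def _ref_strand(base: str, strand: str) -> str:
    return base if strand == "+" else complement(base)


def generate_variants(
    config: SimulationConfig,
    genome: Genome,
    sites: Sequence[PlantedSite] | None = None,
) -> tuple[dict[str, list[VariantRecord]], GroundTruth]:
    """Variant sets per dataset with planted spectrum, mixture and recurrence.

    A ``frac_junction`` share of each dataset lands exactly on junction flank
    positions; the remainder lands elsewhere in the CDS.  Each unique variant
    carries AF, occurrence, tissue, a latent splice-altering flag, per-tool
    scores conditional on that flag, and (for a covered subset) clinical
    category labels.
    """
    config.validate()
    if sites is None:
        sites = genome.junction_sites()
    labels_order = list(POSITIONS)
    pos_w = np.array([config.position_weights[p] for p in labels_order], dtype=float)
    pos_w /= pos_w.sum()
    sub_tables = {
        p: (
            list(config.substitution_enrichment[p].keys()),
            np.array(list(config.substitution_enrichment[p].values()), dtype=float),
        )
        for p in labels_order
    }
    score_rng = config.rng("scores")
    label_rng = config.rng("labels")
    tissue_names = [t for t, _ in config.tissue_labels]
    tissue_w = np.array([w for _, w in config.tissue_labels], dtype=float)
    tissue_w /= tissue_w.sum()

    # background CDS positions (reference-strand ref base), junctions excluded
    site_positions = {(s.contig, s.genomic_position) for s in sites}
    bg_candidates: list[tuple[int, int]] = []  # (gene_index, genomic position)
    for plan in genome.genes:
        for p in plan.cds_genomic_positions:
            if (plan.contig, p) not in site_positions:
                bg_candidates.append((plan.gene_index, p))

    datasets: dict[str, list[VariantRecord]] = {}
    truth_variants: dict[str, list[dict]] = {}
    # the latent splice-altering flag is a property of the variant: a variant
    # present in two datasets must carry one consistent flag
    flag_by_key: dict[tuple, bool] = {}
    for dataset, n_total in config.n_variants_per_dataset.items():
        rng = config.rng(f"variants_{dataset}")
        n_junction = int(round(config.frac_junction * n_total))
        n_background = n_total - n_junction
        if n_junction > 3 * len(sites):
            raise CapacityError(
                f"{dataset}: {n_junction} junction variants requested but only "
                f"{3 * len(sites)} (site, alt) pairs exist"
            )
        pools = _SitePools(sites, rng)
        hot_weight = config.hot_gene_weight if dataset == "cosmic" else 1.0
        records: list[VariantRecord] = []
        truth: list[dict] = []
        for _ in range(n_junction):
            label = labels_order[int(rng.choice(len(labels_order), p=pos_w))]
            subs, weights = sub_tables[label]
            sub = subs[int(rng.choice(len(subs), p=weights / weights.sum()))]
            ref, alt = sub.split(">")
            target = (
                "missense"
                if rng.random() < config.consequence_mix[label]
                else "silent"
            )
            got = pools.take(label, ref, alt, target, hot_weight)
            if got is None:
                continue  # this label/ref class is saturated
            site_idx, alt_used, cons = got
            site = pools.sites[site_idx]
            occurrence = config.recurrence_model.sample(
                rng, hot=site.hot and dataset == "cosmic"
            )
            record = VariantRecord(
                contig=site.contig,
                position=site.genomic_position,
                ref=_ref_strand(site.ref_base, site.strand),
                alt=_ref_strand(alt_used, site.strand),
                dataset=dataset,
                af=config.af_model.sample(rng),
                occurrence=occurrence,
                tissue=(
                    tissue_names[int(rng.choice(len(tissue_names), p=tissue_w))]
                    if dataset == "cosmic"
                    else None
                ),
            )
            draw = rng.random() < config.p_altering.get(dataset, 0.3)
            altering = flag_by_key.setdefault(record.key, draw)
            records.append(record)
            truth.append(
                {
                    "contig": record.contig,
                    "pos": record.position,
                    "ref": record.ref,
                    "alt": record.alt,
                    "gene_id": site.gene_id,
                    "label": site.label,
                    "substitution": f"{site.ref_base}>{alt_used}",
                    "consequence": cons,
                    "is_junction": True,
                    "altering": bool(altering),
                }
            )
        used_bg: set[tuple] = set()
        contig_seq = genome.contigs[config.contig_name]
        attempts = 0
        while len(used_bg) < n_background and attempts < 20 * max(n_background, 1):
            attempts += 1
            gene_index, gpos = bg_candidates[int(rng.integers(len(bg_candidates)))]
            ref = contig_seq[gpos]
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            key = (config.contig_name, gpos, ref, alt)
            if key in used_bg:
                continue
            used_bg.add(key)
            plan = genome.genes[gene_index]
            records.append(
                VariantRecord(
                    contig=config.contig_name,
                    position=gpos,
                    ref=ref,
                    alt=alt,
                    dataset=dataset,
                    af=config.af_model.sample(rng),
                    occurrence=config.recurrence_model.sample(rng, hot=False),
                    tissue=(
                        tissue_names[int(rng.choice(len(tissue_names), p=tissue_w))]
                        if dataset == "cosmic"
                        else None
                    ),
                )
            )
            draw = rng.random() < config.p_altering.get("background", 0.05)
            altering = flag_by_key.setdefault(key, draw)
            truth.append(
                {
                    "contig": config.contig_name,
                    "pos": gpos,
                    "ref": ref,
                    "alt": alt,
                    "gene_id": plan.gene_id,
                    "label": None,
                    "substitution": None,
                    "consequence": None,
                    "is_junction": False,
                    "altering": bool(altering),
                }
            )
        datasets[dataset] = records
        truth_variants[dataset] = truth

    # scores and labels, conditional on the latent flag, one stream for all
    for dataset, records in datasets.items():
        truth = truth_variants[dataset]
        for record, t in zip(records, truth):
            for tool, model in config.score_models.items():
                value = model.sample(score_rng, altering=t["altering"])
                if value is not None:
                    record.scores[tool] = value
            if label_rng.random() < config.validated_label_fraction:
                record.labels["splice_altering"] = "1" if t["altering"] else "0"
            if label_rng.random() < config.clinvar_coverage:
                names = list(config.clinvar_probs)
                probs = np.array(list(config.clinvar_probs.values()))
                record.labels["clinvar"] = names[
                    int(label_rng.choice(len(names), p=probs / probs.sum()))
                ]
            if label_rng.random() < config.splicevardb_coverage:
                names = list(config.splicevardb_probs)
                probs = np.array(list(config.splicevardb_probs.values()))
                record.labels["splicevardb"] = names[
                    int(label_rng.choice(len(names), p=probs / probs.sum()))
                ]

    loeuf_rng = config.rng("loeuf")
    genes_truth: dict[str, dict] = {}
    for plan in genome.genes:
        genes_truth[plan.gene_id] = {
            "gene_name": plan.gene_name,
            "hot": plan.hot,
            "exon_count": plan.exon_count,
            "loeuf": config.loeuf_model.sample(loeuf_rng, plan.hot),
            "sets": [],
        }
    set_rng = config.rng("genesets")
    gene_ids = [p.gene_id for p in genome.genes]
    hot_w = np.array(
        [config.gene_set_hot_weight if p.hot else 1.0 for p in genome.genes]
    )
    for set_name, frac in config.gene_set_fractions.items():
        size = max(1, int(round(frac * len(gene_ids))))
        chosen = set_rng.choice(
            len(gene_ids), size=size, replace=False, p=hot_w / hot_w.sum()
        )
        for idx in chosen:
            genes_truth[gene_ids[int(idx)]]["sets"].append(set_name)

    truth_obj = GroundTruth(
        sites=[
            {
                "contig": s.contig,
                "pos": s.genomic_position,
                "strand": s.strand,
                "role": s.role,
                "offset": s.offset,
                "ref_base": s.ref_base,
                "gene_id": s.gene_id,
            }
            for s in sites
        ],
        variants=truth_variants,
        genes=genes_truth,
        planted={
            "substitution_enrichment": config.substitution_enrichment,
            "exonic_consensus": config.exonic_consensus,
            "consequence_mix": config.consequence_mix,
            "position_weights": {
                p: w / sum(config.position_weights.values())
                for p, w in config.position_weights.items()
            },
            "p_altering": config.p_altering,
            "recurrence_q": config.recurrence_model.q,
            "recurrence_q_hot": config.recurrence_model.q_hot,
        },
    )
    return datasets, truth_obj


def conservation_scores(
    config: SimulationConfig,
    genome: Genome,
    datasets: Mapping[str, Sequence[VariantRecord]],
) -> dict[tuple[str, int], float]:
    """Per-site conservation probabilities: near 1 where cancer variants sit,
    broad where only population variants sit, mid elsewhere."""
    rng = config.rng("conservation")
    cosmic_positions = {
        (v.contig, v.position) for v in datasets.get("cosmic", [])
    }
    gnomad_positions = {
        (v.contig, v.position)
        for name, records in datasets.items()
        if name.startswith("gnomad")
        for v in records
    }
    out: dict[tuple[str, int], float] = {}
    for site in genome.junction_sites():
        key = (site.contig, site.genomic_position)
        if key in out:
            continue
        if key in cosmic_positions:
            value = rng.beta(60.0, 1.0)
        elif key in gnomad_positions:
            value = rng.beta(1.1, 0.9)
        else:
            value = rng.beta(2.0, 2.0)
        out[key] = float(min(value, 1.0))
    return out


# ---------------------------------------------------------------------------
# writers


def write_vcf(
    records: Sequence[VariantRecord], genome: Genome, path: str | Path
) -> None:
    rows = sorted(records, key=lambda v: (v.contig, v.position, v.ref, v.alt))
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for name in sorted(genome.contigs):
            handle.write(f"##contig=<ID={name},length={len(genome.contigs[name])}>\n")
        handle.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        handle.write('##INFO=<ID=OCC,Number=1,Type=Integer,Description="Occurrence count">\n')
        handle.write('##INFO=<ID=TISSUE,Number=1,Type=String,Description="Tissue label">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in rows:
            info = [f"OCC={v.occurrence}"]
            if v.af is not None:
                info.insert(0, f"AF={v.af:.6g}")
            if v.tissue is not None:
                info.append(f"TISSUE={v.tissue}")
            handle.write(
                f"{v.contig}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                + ";".join(info)
                + "\n"
            )


def write_variant_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = sorted(records, key=lambda v: (v.contig, v.position, v.ref, v.alt))
    with open(path, "w") as handle:
        handle.write("chrom\tpos\tref\talt\taf\toccurrence\ttissue\n")
        for v in rows:
            af = "" if v.af is None else f"{v.af:.6g}"
            tissue = v.tissue or ""
            handle.write(
                f"{v.contig}\t{v.position + 1}\t{v.ref}\t{v.alt}\t{af}\t"
                f"{v.occurrence}\t{tissue}\n"
            )


def write_scores_tsv(
    datasets: Mapping[str, Sequence[VariantRecord]],
    tools: Sequence[str],
    path: str | Path,
) -> None:
    seen: set[tuple] = set()
    rows = []
    for records in datasets.values():
        for v in records:
            if v.key in seen or not v.scores:
                continue
            seen.add(v.key)
            rows.append(v)
    rows.sort(key=lambda v: (v.contig, v.position, v.ref, v.alt))
    with open(path, "w") as handle:
        handle.write("chrom\tpos\tref\talt\t" + "\t".join(tools) + "\n")
        for v in rows:
            values = [
                f"{v.scores[t]:.6g}" if t in v.scores else "" for t in tools
            ]
            handle.write(
                f"{v.contig}\t{v.position + 1}\t{v.ref}\t{v.alt}\t"
                + "\t".join(values)
                + "\n"
            )


def write_labels_tsv(
    datasets: Mapping[str, Sequence[VariantRecord]], name: str, path: str | Path
) -> None:
    seen: set[tuple] = set()
    rows = []
    for records in datasets.values():
        for v in records:
            if v.key in seen or name not in v.labels:
                continue
            seen.add(v.key)
            rows.append(v)
    rows.sort(key=lambda v: (v.contig, v.position, v.ref, v.alt))
    with open(path, "w") as handle:
        handle.write("chrom\tpos\tref\talt\tlabel\n")
        for v in rows:
            handle.write(
                f"{v.contig}\t{v.position + 1}\t{v.ref}\t{v.alt}\t{v.labels[name]}\n"
            )


def write_loeuf_tsv(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tloeuf\n")
        for gene_id in sorted(truth.genes):
            value = truth.genes[gene_id]["loeuf"]
            if value is not None:
                handle.write(f"{gene_id}\t{value:.4f}\n")


def write_gene_sets(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    members: dict[str, list[str]] = {}
    for gene_id in sorted(truth.genes):
        for set_name in truth.genes[gene_id]["sets"]:
            members.setdefault(set_name, []).append(gene_id)
    paths = {}
    for set_name, genes in sorted(members.items()):
        path = outdir / f"{set_name.lower()}.txt"
        path.write_text("\n".join(genes) + "\n")
        paths[set_name] = path
    return paths


def write_conservation(
    scores: Mapping[tuple[str, int], float], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for (contig, pos), value in sorted(scores.items()):
            handle.write(f"{contig}\t{pos}\t{pos + 1}\t{value:.4f}\n")


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run the whole generator and write every artifact into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    genome.write_fasta(outdir / "genome.fa")
    generate_annotation(config, genome, outdir / "annotation.gtf")
    datasets, truth = generate_variants(config, genome)
    tools = list(config.score_models)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "scores": outdir / "scores.tsv",
        "loeuf": outdir / "loeuf.tsv",
        "conservation": outdir / "phastcons.bedgraph",
        "ground_truth": outdir / "ground_truth.json",
    }
    for dataset, records in datasets.items():
        write_vcf(records, genome, outdir / f"{dataset}.vcf")
        write_variant_tsv(records, outdir / f"{dataset}.tsv")
        paths[f"{dataset}_vcf"] = outdir / f"{dataset}.vcf"
        paths[f"{dataset}_tsv"] = outdir / f"{dataset}.tsv"
    write_scores_tsv(datasets, tools, paths["scores"])
    for label_name in ("splice_altering", "clinvar", "splicevardb"):
        write_labels_tsv(datasets, label_name, outdir / f"labels_{label_name}.tsv")
        paths[f"labels_{label_name}"] = outdir / f"labels_{label_name}.tsv"
    write_loeuf_tsv(truth, paths["loeuf"])
    paths.update(write_gene_sets(truth, outdir))
    cons = conservation_scores(config, genome, datasets)
    write_conservation(cons, paths["conservation"])
    truth.to_json(paths["ground_truth"])
    return {"paths": paths, "genome": genome, "datasets": datasets, "truth": truth}


# ---------------------------------------------------------------------------
# gene-level shortcut sharing the same planted models, for replicated power
# studies of the constraint-enrichment stage without re-simulating genomes


def gene_level_replicate(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, list[str]], dict[str, float], dict[str, bool]]:
    """Per-gene unique-variant counts under the planted hot-gene/LOEUF models.

    Cancer variants prefer hot (low-LOEUF-enriched) genes by
    ``hot_gene_weight``; population variants are spread uniformly.  Returns
    ranked gene lists per dataset, the LOEUF table, and the hot flags.
    """
    rng = np.random.default_rng([seed, 997])
    n = config.n_genes
    hot = rng.random(n) < config.hot_gene_fraction
    gene_ids = [f"G{i:05d}" for i in range(n)]
    exon_counts = rng.integers(
        config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1, n
    )
    loeuf = {}
    for i in range(n):
        value = config.loeuf_model.sample(rng, bool(hot[i]))
        if value is not None:
            loeuf[gene_ids[i]] = value

    from .enrichment import GeneSummary, rank_top_genes

    ranked: dict[str, list[str]] = {}
    for dataset, n_total in config.n_variants_per_dataset.items():
        n_junction = int(round(config.frac_junction * n_total))
        weights = np.where(hot, config.hot_gene_weight if dataset == "cosmic" else 1.0, 1.0)
        counts = rng.multinomial(n_junction, weights / weights.sum())
        summaries = [
            GeneSummary(
                gene_id=gene_ids[i],
                exon_count=int(exon_counts[i]),
                counts={"d1": int(counts[i])},
            )
            for i in range(n)
        ]
        top = rank_top_genes(summaries, m=100, floor=0.4)
        ranked[dataset] = [s.gene_id for s in top]
    return ranked, loeuf, {gene_ids[i]: bool(hot[i]) for i in range(n)}
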