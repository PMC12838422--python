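"""Variant ingestion, filtering, junction assignment and consequence calling.

SNVs are read from VCF or COSMIC/gnomAD-style TSV, filtered on population
allele frequency (0.1% cutoff), joined to junction sites with coding-strand
substitution normalisation, and classified silent / missense / nonsense /
other by codon translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio.Data import CodonTable

from .errors import (
    AnnotationError,
    OutOfCdsError,
    SpliceflankError,
    ValidationError,
)
from .junctions import JunctionSite, SiteIndex, TranscriptModel, complement, revcomp

log = logging.getLogger(__name__)

SUBSTITUTIONS = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)  # 12 ordered types on the coding strand

CONSEQUENCES = ("silent", "missense", "nonsense", "other")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """Amino acid for one codon under the standard nuclear code; '*' for stop."""
    codon = codon.upper()
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass
class VariantRecord:
    contig: str
    position: int  # 0-based internal
    ref: str
    alt: str
    dataset: str = "other"  # cosmic | gnomad_rare | gnomad_common | gnomad | other
    af: float | None = None
    occurrence: int = 1
    tissue: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.contig}:{self.position} ref equals alt ({self.ref})"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass
class AnnotatedJunctionVariant:
    """A variant joined to one junction-site label."""

    variant: VariantRecord
    site: JunctionSite
    coding_ref: str
    coding_alt: str
    consequence: str | None = None
    gene_id: str | None = None

    @property
    def substitution(self) -> str:
        return f"{self.coding_ref}>{self.coding_alt}"

    @property
    def position_label(self) -> str:
        return self.site.label

    @property
    def key(self) -> tuple:
        return self.variant.key

    @property
    def site_key(self) -> tuple:
        return self.site.key


@dataclass
class RecurrenceTable:
    counts: dict[tuple, int]

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def fraction_at_least(self, k: int) -> float:
        if not self.counts:
            return 0.0
        return sum(1 for c in self.counts.values() if c >= k) / len(self.counts)

    def strata(self) -> dict[str, int]:
        vals = list(self.counts.values())
        return {
            "1": sum(1 for c in vals if c == 1),
            ">=2": sum(1 for c in vals if c >= 2),
            ">=5": sum(1 for c in vals if c >= 5),
        }


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT"


def read_variants(
    path: str,
    dialect: str,
    dataset: str | None = None,
    fasta: Mapping[str, object] | None = None,
) -> list[VariantRecord]:
    """Read SNVs from ``vcf``, ``cosmic_tsv`` or ``gnomad_tsv`` files.

    Coordinates are normalised to internal 0-based, multi-allelic VCF rows are
    split one record per alt, and non-SNVs are dropped (their count is logged).
    When a FASTA mapping is provided, reference bases are validated against it.
    """
    if dialect not in ("vcf", "cosmic_tsv", "gnomad_tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    if dataset is None:
        dataset = {"cosmic_tsv": "cosmic", "gnomad_tsv": "gnomad", "vcf": "other"}[dialect]

    records: list[VariantRecord] = []
    n_dropped = 0
    if dialect == "vcf":
        with pysam.VariantFile(path) as vcf:
            for row in vcf:
                info = dict(row.info)
                for alt in row.alts or ():
                    if not _is_snv(row.ref, alt):
                        n_dropped += 1
                        continue
                    af = info.get("AF")
                    if isinstance(af, tuple):
                        af = af[0]
                    records.append(
                        VariantRecord(
                            contig=row.contig,
                            position=row.pos - 1,
                            ref=row.ref,
                            alt=alt,
                            dataset=dataset,
                            af=float(af) if af is not None else None,
                            occurrence=int(info.get("OCC", 1)),
                            tissue=info.get("TISSUE"),
                        )
                    )
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "pos", "ref", "alt"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for row in frame.itertuples(index=False):
            ref, alt = str(row.ref), str(row.alt)
            if not _is_snv(ref, alt):
                n_dropped += 1
                continue
            af = getattr(row, "af", None)
            occurrence = getattr(row, "occurrence", 1)
            tissue = getattr(row, "tissue", None)
            records.append(
                VariantRecord(
                    contig=str(row.chrom),
                    position=int(row.pos) - 1,
                    ref=ref,
                    alt=alt,
                    dataset=dataset,
                    af=None if pd.isna(af) else float(af),
                    occurrence=1 if pd.isna(occurrence) else int(occurrence),
                    tissue=None if tissue is None or pd.isna(tissue) else str(tissue),
                )
            )
    if n_dropped:
        log.info("%s: dropped %d non-SNV records", path, n_dropped)
    if fasta is not None:
        bad = []
        for rec in records:
            seq = fasta[rec.contig]
            base = (
                seq[rec.position]
                if isinstance(seq, str)
                else str(seq[rec.position])
            ).upper()
            if base != rec.ref:
                bad.append(f"{rec.contig}:{rec.position + 1} ref {rec.ref} != FASTA {base}")
        if bad:
            raise ValidationError("reference mismatches:\n" + "\n".join(bad[:20]))
    return records


def filter_population(
    variants: Iterable[VariantRecord], af_cutoff: float = 0.001
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Apply the population allele-frequency cutoff (default 0.1%).

    COSMIC records at or above the cutoff are removed (common in the healthy
    population); gnomAD records are split into ``gnomad_rare`` (< cutoff) and
    ``gnomad_common`` (>= cutoff).  A missing AF counts as 0.
    """
    kept, removed = [], []
    for v in variants:
        af = 0.0 if v.af is None else v.af
        if v.dataset == "cosmic":
            (removed if af >= af_cutoff else kept).append(v)
        elif v.dataset in ("gnomad", "gnomad_rare", "gnomad_common"):
            v.dataset = "gnomad_common" if af >= af_cutoff else "gnomad_rare"
            kept.append(v)
        else:
            kept.append(v)
    return kept, removed


def assign_to_junctions(
    variants: Iterable[VariantRecord], site_index: SiteIndex
) -> list[AnnotatedJunctionVariant]:
    """Join variants to junction sites by exact position.

    One output record per (variant, matching site label); substitutions are
    reverse-complemented onto the coding strand for minus-strand sites.
    Variants hitting no site are silently excluded.
    """
    out = []
    for v in variants:
        for site in site_index.lookup(v.contig, v.position):
            if site.strand == "-":
                coding_ref, coding_alt = complement(v.ref), complement(v.alt)
            else:
                coding_ref, coding_alt = v.ref, v.alt
            if coding_ref != site.ref_base:
                raise ValidationError(
                    f"{v.contig}:{v.position + 1} ref {v.ref} (coding {coding_ref}) "
                    f"disagrees with site ref_base {site.ref_base} at {site.label}"
                )
            out.append(
                AnnotatedJunctionVariant(
                    variant=v,
                    site=site,
                    coding_ref=coding_ref,
                    coding_alt=coding_alt,
                    gene_id=site.gene_ids[0],
                )
            )
    return out


def _spliced_cds(transcript: TranscriptModel) -> tuple[list[int], str | None]:
    """Genomic positions of the spliced CDS in coding order (sequence fetched lazily)."""
    positions: list[int] = []
    for s, e in transcript.cds:
        positions.extend(range(s, e))
    if transcript.strand == "-":
        positions.reverse()
    return positions, None


def call_consequence(
    variant: VariantRecord,
    transcript: TranscriptModel,
    genome: Mapping[str, object],
) -> str:
    """Classify an SNV by translating its ref and alt codons.

    Same amino acid -> silent; different, neither stop -> missense; alt codon
    stop -> nonsense; ref codon stop -> other.
    """
    positions, _ = _spliced_cds(transcript)
    if len(positions) % 3 != 0:
        raise AnnotationError(
            f"{transcript.transcript_id}: CDS length {len(positions)} not divisible by 3"
        )
    try:
        cds_index = positions.index(variant.position)
    except ValueError:
        raise OutOfCdsError(
            f"{variant.contig}:{variant.position + 1} not in CDS of "
            f"{transcript.transcript_id}"
        ) from None
    seq = genome[transcript.contig]

    def base_at(genomic_pos: int) -> str:
        b = seq[genomic_pos] if isinstance(seq, str) else str(seq[genomic_pos])
        return b.upper()

    codon_start = 3 * (cds_index // 3)
    codon_positions = positions[codon_start : codon_start + 3]
    codon = "".join(
        complement(base_at(p)) if transcript.strand == "-" else base_at(p)
        for p in codon_positions
    )
    pos_in_codon = cds_index % 3
    coding_ref = complement(variant.ref) if transcript.strand == "-" else variant.ref
    coding_alt = complement(variant.alt) if transcript.strand == "-" else variant.alt
    if codon[pos_in_codon] != coding_ref:
        raise ValidationError(
            f"{variant.contig}:{variant.position + 1} coding ref {coding_ref} "
            f"does not match transcript codon base {codon[pos_in_codon]}"
        )
    alt_codon = codon[:pos_in_codon] + coding_alt + codon[pos_in_codon + 1 :]
    ref_aa, alt_aa = translate_codon(codon), translate_codon(alt_codon)
    if ref_aa == "*":
        return "other"
    if alt_aa == "*":
        return "nonsense"
    return "silent" if ref_aa == alt_aa else "missense"


def annotate_consequences(
    annotated: Iterable[AnnotatedJunctionVariant],
    transcripts_by_gene: Mapping[str, TranscriptModel],
    genome: Mapping[str, object],
) -> list[AnnotatedJunctionVariant]:
    """Fill the consequence field of junction-assigned variants in place."""
    out = []
    for av in annotated:
        transcript = transcripts_by_gene.get(av.gene_id)
        if transcript is None:
            raise ValidationError(f"no transcript for gene {av.gene_id}")
        av.consequence = call_consequence(av.variant, transcript, genome)
        out.append(av)
    return out


def recurrence(
    variants: Iterable[VariantRecord] | Iterable[AnnotatedJunctionVariant],
) -> RecurrenceTable:
    """Summed occurrence per unique variant key (contig, pos, ref, alt)."""
    counts: dict[tuple, int] = {}
    seen_rows: set[tuple] = set()
    for item in variants:
        v = item.variant if isinstance(item, AnnotatedJunctionVariant) else item
        # a variant annotated against several site labels still counts once
        row_id = (id(v),)
        if row_id in seen_rows:
            continue
        seen_rows.add(row_id)
        counts[v.key] = counts.get(v.key, 0) + v.occurrence
    return RecurrenceTable(counts=counts)


def annotated_to_frame(annotated: Sequence[AnnotatedJunctionVariant]) -> pd.DataFrame:
    """Flat table of annotated variants (positions written 1-based)."""
    rows = []
    for av in annotated:
        v = av.variant
        row = {
            "contig": v.contig,
            "pos": v.position + 1,
            "ref": v.ref,
            "alt": v.alt,
            "strand": av.site.strand,
            "gene": av.gene_id,
            "role": av.site.role,
            "offset": av.site.offset,
            "position_label": av.position_label,
            "substitution": av.substitution,
            "consequence": av.consequence,
            "dataset": v.dataset,
            "af": v.af,
            "occurrence": v.occurrence,
            "tissue": v.tissue,
        }
        for tool, score in v.scores.items():
            row[f"score_{tool}"] = score
        for name, label in v.labels.items():
            row[f"label_{name}"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def attach_scores(
    variants: Iterable[VariantRecord], scores_frame: pd.DataFrame
) -> None:
    """Merge a wide per-tool score table (chrom, pos 1-based, ref, alt, tool...)."""
    meta = {"chrom", "pos", "ref", "alt"}
    missing = meta - set(scores_frame.columns)
    if missing:
        raise ValidationError(f"score table missing columns {sorted(missing)}")
    tools = [c for c in scores_frame.columns if c not in meta]
    lookup: dict[tuple, dict[str, float]] = {}
    for row in scores_frame.itertuples(index=False):
        key = (str(row.chrom), int(row.pos) - 1, str(row.ref), str(row.alt))
        lookup[key] = {
            t: float(getattr(row, t))
            for t in tools
            if not pd.isna(getattr(row, t))
        }
    for v in variants:
        v.scores.update(lookup.get(v.key, {}))


def attach_labels(
    variants: Iterable[VariantRecord], labels_frame: pd.DataFrame, name: str
) -> None:
    """Merge a per-variant categorical label column under the given name."""
    required = {"chrom", "pos", "ref", "alt", "label"}
    missing = required - set(labels_frame.columns)
    if missing:
        raise ValidationError(f"label table missing columns {sorted(missing)}")
    lookup = {
        (str(r.chrom), int(r.pos) - 1, str(r.ref), str(r.alt)): str(r.label)
        for r in labels_frame.itertuples(index=False)
    }
    for v in variants:
        label = lookup.get(v.key)
        if label is not None:
            v.labels[name] = label
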