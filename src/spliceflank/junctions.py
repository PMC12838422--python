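"""Junction-site derivation from gene annotation.

Parses GENCODE-dialect GTF, selects one canonical protein-coding transcript
per gene, trims UTRs away, and derives the three exonic nucleotides flanking
each splice donor (d1-d3, the last bases of an exon) and acceptor (a1-a3, the
first bases of an exon).  Position labels and reference bases are defined on
the coding (transcript) strand; internal coordinates are 0-based half-open,
GTF I/O is 1-based inclusive and BED I/O is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import (
    CoordinateError,
    EmptyInputError,
    GtfParseError,
    SpliceflankError,
)

POSITIONS = ("d1", "d2", "d3", "a1", "a2", "a3")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


@dataclass
class TranscriptModel:
    """One transcript: exons and CDS intervals in genomic order (0-based half-open)."""

    transcript_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    canonical_flag: bool = False

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class CodingExon:
    """A UTR-trimmed exon with its 1-based rank in transcript orientation."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    rank_in_transcript: int
    is_first: bool
    is_last: bool

    def __post_init__(self):
        if self.end <= self.start:
            raise CoordinateError(
                f"coding exon [{self.start},{self.end}) has length < 1"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionSite:
    """One genomic position labelled with splice role and exonic offset.

    ``ref_base`` is the base on the coding strand (reverse complement of the
    reference base for minus-strand transcripts).
    """

    contig: str
    genomic_position: int
    strand: str
    role: str  # donor | acceptor
    offset: int  # 1..3
    ref_base: str
    exon_key: str
    gene_ids: tuple[str, ...]

    @property
    def label(self) -> str:
        return ("d" if self.role == "donor" else "a") + str(self.offset)

    @property
    def key(self) -> tuple:
        return (self.contig, self.genomic_position, self.strand, self.role, self.offset)


@dataclass
class SiteIndex:
    """Non-redundant junction-site set with exact-position lookup."""

    sites: dict[tuple, JunctionSite] = field(default_factory=dict)
    by_position: dict[tuple[str, int], list[JunctionSite]] = field(default_factory=dict)

    def add(self, site: JunctionSite) -> None:
        key = site.key
        existing = self.sites.get(key)
        if existing is None:
            self.sites[key] = site
            self.by_position.setdefault(
                (site.contig, site.genomic_position), []
            ).append(site)
        else:
            genes = tuple(sorted(set(existing.gene_ids) | set(site.gene_ids)))
            merged = replace(existing, gene_ids=genes)
            self.sites[key] = merged
            pos_list = self.by_position[(site.contig, site.genomic_position)]
            pos_list[pos_list.index(existing)] = merged

    def lookup(self, contig: str, position: int) -> list[JunctionSite]:
        return self.by_position.get((contig, position), [])

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites.values())


_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, line_no: int) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    found = _ATTR_RE.findall(attr_field)
    if not found and attr_field.strip():
        raise GtfParseError(f"line {line_no}: malformed attribute string: {attr_field!r}")
    for key, value in found:
        attrs.setdefault(key, []).append(value)
    return attrs


def parse_gtf(path: str, canonical_tag: str = "Ensembl_canonical") -> list[TranscriptModel]:
    """Read a GENCODE-dialect GTF into transcript models.

    Keeps only ``transcript_type "protein_coding"`` transcripts that carry at
    least one CDS record.  GTF 1-based inclusive coordinates are converted to
    internal 0-based half-open ones.  ``canonical_tag`` names the transcript
    tag that marks the representative isoform.
    """
    transcripts: dict[str, TranscriptModel] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {line_no}: expected 9 tab-separated fields, got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("transcript", "exon", "CDS"):
                continue
            try:
                start_1, end_1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {line_no}: non-integer coordinates") from exc
            if end_1 < start_1:
                raise CoordinateError(
                    f"line {line_no}: end {end_1} < start {start_1}"
                )
            attrs = _parse_attributes(attr, line_no)
            try:
                tid = attrs["transcript_id"][0]
            except KeyError as exc:
                raise GtfParseError(f"line {line_no}: missing transcript_id") from exc
            ttype = attrs.get("transcript_type", ["protein_coding"])[0]
            if ttype != "protein_coding":
                continue
            interval = (start_1 - 1, end_1)  # 1-based inclusive -> 0-based half-open
            model = transcripts.get(tid)
            if model is None:
                model = TranscriptModel(
                    transcript_id=tid,
                    gene_id=attrs.get("gene_id", [tid])[0],
                    gene_name=attrs.get("gene_name", attrs.get("gene_id", [tid]))[0],
                    contig=contig,
                    strand=strand,
                )
                transcripts[tid] = model
            if feature == "transcript":
                model.canonical_flag = model.canonical_flag or (
                    canonical_tag in attrs.get("tag", [])
                )
            elif feature == "exon":
                model.exons.append(interval)
            elif feature == "CDS":
                model.cds.append(interval)
    out = []
    for model in transcripts.values():
        if not model.cds:
            continue  # contract: transcripts with no CDS are dropped
        model.exons.sort()
        model.cds.sort()
        out.append(model)
    return out


def select_canonical(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep exactly one transcript per gene.

    The one tagged canonical wins; otherwise the longest total CDS, ties broken
    by lexicographically smallest transcript_id.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    chosen = []
    for gene_id in sorted(by_gene):
        candidates = by_gene[gene_id]
        tagged = [t for t in candidates if t.canonical_flag]
        pool = tagged if tagged else candidates
        pool.sort(key=lambda t: (-t.cds_length, t.transcript_id))
        chosen.append(pool[0])
    return chosen


def _intersect(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    return (s, e) if s < e else None


def trim_to_cds(transcript: TranscriptModel) -> list[CodingExon]:
    """Intersect exons with CDS and rank the survivors in transcript orientation."""
    trimmed: list[tuple[int, int]] = []
    for exon in transcript.exons:
        pieces = [iv for cds in transcript.cds if (iv := _intersect(exon, cds))]
        if not pieces:
            continue  # pure-UTR exon
        trimmed.append((min(s for s, _ in pieces), max(e for _, e in pieces)))
    trimmed.sort()
    if transcript.strand == "-":
        ordered = list(reversed(trimmed))
    else:
        ordered = trimmed
    n = len(ordered)
    return [
        CodingExon(
            transcript_id=transcript.transcript_id,
            gene_id=transcript.gene_id,
            contig=transcript.contig,
            strand=transcript.strand,
            start=s,
            end=e,
            rank_in_transcript=i + 1,
            is_first=(i == 0),
            is_last=(i == n - 1),
        )
        for i, (s, e) in enumerate(ordered)
    ]


def _fetch_base(genome, contig: str, pos: int) -> str:
    """One reference base; accepts a mapping of strings or a pyfaidx.Fasta."""
    seq = genome[contig]
    if isinstance(seq, str):
        if pos < 0 or pos >= len(seq):
            raise CoordinateError(f"{contig}:{pos} outside contig bounds")
        return seq[pos].upper()
    length = len(seq)
    if pos < 0 or pos >= length:
        raise CoordinateError(f"{contig}:{pos} outside contig bounds")
    return str(seq[pos]).upper()


def _site_pos(exon: CodingExon, role: str, offset: int) -> int:
    # donor counts back from the transcript-orientation exon end, acceptor
    # forward from the exon start; both flip on the minus strand
    if role == "donor":
        return exon.end - offset if exon.strand == "+" else exon.start + (offset - 1)
    return exon.start + (offset - 1) if exon.strand == "+" else exon.end - offset


def derive_junction_sites(
    coding_exons: Iterable[CodingExon], genome: Mapping[str, object]
) -> list[JunctionSite]:
    """Exonic donor (d1-d3) and acceptor (a1-a3) sites of a set of coding exons.

    Every non-last exon (transcript orientation) yields donor sites, every
    non-first exon acceptor sites; offsets are clamped to the exon length, so a
    2 bp micro-exon emits only offsets 1-2 on each applicable side and a
    single-exon transcript emits nothing.
    """
    sites = []
    for exon in coding_exons:
        roles = []
        if not exon.is_last:
            roles.append("donor")
        if not exon.is_first:
            roles.append("acceptor")
        for role in roles:
            for offset in (1, 2, 3):
                if offset > exon.length:
                    break
                pos = _site_pos(exon, role, offset)
                base = _fetch_base(genome, exon.contig, pos)
                if exon.strand == "-":
                    base = complement(base)
                sites.append(
                    JunctionSite(
                        contig=exon.contig,
                        genomic_position=pos,
                        strand=exon.strand,
                        role=role,
                        offset=offset,
                        ref_base=base,
                        exon_key=f"{exon.transcript_id}:{exon.rank_in_transcript}",
                        gene_ids=(exon.gene_id,),
                    )
                )
    return sites


def collapse_nonredundant(sites: Iterable[JunctionSite]) -> SiteIndex:
    """Merge duplicate (contig, position, strand, role, offset) labels.

    Gene lists are unioned.  A position shared by the donor of one exon and the
    acceptor of another keeps both entries.
    """
    index = SiteIndex()
    for site in sites:
        index.add(site)
    return index


def write_sites_bed(site_index: SiteIndex, path: str) -> None:
    """BED6 export, one line per non-redundant site.

    Name packs ``genes|role:label|ref_base`` so the file round-trips losslessly.
    """
    if len(site_index) == 0:
        raise EmptyInputError("refusing to write an empty site index")
    rows = sorted(
        site_index,
        key=lambda s: (s.contig, s.genomic_position, s.strand, s.role, s.offset),
    )
    with open(path, "w") as handle:
        for s in rows:
            name = f"{','.join(s.gene_ids)}|{s.role}:{s.label}|{s.ref_base}"
            handle.write(
                f"{s.contig}\t{s.genomic_position}\t{s.genomic_position + 1}"
                f"\t{name}\t0\t{s.strand}\n"
            )


def read_sites_bed(path: str) -> SiteIndex:
    """Inverse of :func:`write_sites_bed`."""
    index = SiteIndex()
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise SpliceflankError(f"line {line_no}: not BED6")
            contig, start, end, name, _score, strand = fields
            genes, role_label, ref_base = name.split("|")
            role, label = role_label.split(":")
            index.add(
                JunctionSite(
                    contig=contig,
                    genomic_position=int(start),
                    strand=strand,
                    role=role,
                    offset=int(label[1]),
                    ref_base=ref_base,
                    exon_key="",
                    gene_ids=tuple(genes.split(",")),
                )
            )
            if int(end) != int(start) + 1:
                raise CoordinateError(f"line {line_no}: site interval must be 1 bp")
    return index


def sites_from_annotation(
    transcripts: Iterable[TranscriptModel], genome: Mapping[str, object]
) -> SiteIndex:
    """Canonical selection + UTR trimming + derivation + collapse in one call."""
    canonical = select_canonical(transcripts)
    sites: list[JunctionSite] = []
    for t in canonical:
        sites.extend(derive_junction_sites(trim_to_cds(t), genome))
    return collapse_nonredundant(sites)
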