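"""Variant ingestion, AF filtering, junction assignment, consequence calling
and recurrence tallies."""

import numpy as np
import pytest

from spliceflank.errors import (
    AnnotationError,
    OutOfCdsError,
    ValidationError,
)
from spliceflank.junctions import (
    TranscriptModel,
    collapse_nonredundant,
    derive_junction_sites,
    trim_to_cds,
)
from spliceflank.variants import (
    VariantRecord,
    assign_to_junctions,
    call_consequence,
    filter_population,
    read_variants,
    recurrence,
)

from oracles import protein_consequence, reflect_locus


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=c1,length=1000>\n"
    '##INFO=<ID=AF,Number=1,Type=Float,Description="af">\n'
    '##INFO=<ID=OCC,Number=1,Type=Integer,Description="occ">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestReadVariants:
    def test_vcf_position_converted(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(VCF_HEADER + "c1\t200\t.\tG\tT\t.\t.\tAF=0.0001;OCC=3\n")
        (rec,) = read_variants(str(path), "vcf", dataset="cosmic")
        assert rec.position == 199
        assert rec.occurrence == 3
        assert rec.af == pytest.approx(0.0001)

    def test_multiallelic_split(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(VCF_HEADER + "c1\t200\t.\tG\tA,T\t.\t.\tOCC=1\n")
        records = read_variants(str(path), "vcf")
        assert [(r.ref, r.alt) for r in records] == [("G", "A"), ("G", "T")]

    def test_non_snv_dropped(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            VCF_HEADER
            + "c1\t200\t.\tGT\tG\t.\t.\tOCC=1\n"
            + "c1\t300\t.\tC\tA\t.\t.\tOCC=1\n"
        )
        records = read_variants(str(path), "vcf")
        assert len(records) == 1 and records[0].ref == "C"

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\taf\toccurrence\ttissue\n"
            "c1\t200\tG\tT\t\t4\tskin\n"
        )
        (rec,) = read_variants(str(path), "cosmic_tsv")
        assert (rec.position, rec.af, rec.occurrence, rec.tissue) == (199, None, 4, "skin")
        assert rec.dataset == "cosmic"

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValidationError):
            read_variants(str(tmp_path / "x"), "excel")

    def test_ref_mismatch_against_fasta(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("chrom\tpos\tref\talt\nc1\t3\tG\tT\n")
        with pytest.raises(ValidationError, match="mismatch"):
            read_variants(str(path), "cosmic_tsv", fasta={"c1": "AAAAA"})

    def test_record_count_matches_ground_truth(self, small_sim):
        records = read_variants(str(small_sim["paths"]["cosmic_tsv"]), "cosmic_tsv")
        assert len(records) == len(small_sim["truth"].variants["cosmic"])


class TestFilterPopulation:
    def test_common_cosmic_removed(self):
        kept, removed = filter_population(
            [VariantRecord("c1", 0, "G", "T", dataset="cosmic", af=0.05)]
        )
        assert kept == [] and len(removed) == 1

    def test_missing_af_kept(self):
        kept, _ = filter_population(
            [VariantRecord("c1", 0, "G", "T", dataset="cosmic", af=None)]
        )
        assert len(kept) == 1

    def test_gnomad_boundary_goes_to_common(self):
        kept, _ = filter_population(
            [VariantRecord("c1", 0, "G", "T", dataset="gnomad", af=0.001)]
        )
        assert kept[0].dataset == "gnomad_common"

    def test_gnomad_below_cutoff_is_rare(self):
        kept, _ = filter_population(
            [VariantRecord("c1", 0, "G", "T", dataset="gnomad", af=0.0009)]
        )
        assert kept[0].dataset == "gnomad_rare"


class TestAssign:
    def _index(self, toy_genome):
        sites = []
        for key in ("plus", "minus"):
            sites += derive_junction_sites(
                trim_to_cds(toy_genome[key]), toy_genome["contigs"]
            )
        return collapse_nonredundant(sites)

    def test_plus_strand_substitution(self, toy_genome):
        index = self._index(toy_genome)
        d1 = next(
            s for s in index
            if s.strand == "+" and s.role == "donor" and s.offset == 1
        )
        ref = toy_genome["contigs"]["c1"][d1.genomic_position]
        alt = "T" if ref != "T" else "A"
        (av,) = assign_to_junctions(
            [VariantRecord("c1", d1.genomic_position, ref, alt)], index
        )
        assert av.substitution == f"{ref}>{alt}"

    def test_minus_strand_substitution_reverse_complemented(self, toy_genome):
        index = self._index(toy_genome)
        d1 = next(
            s for s in index
            if s.strand == "-" and s.role == "donor" and s.offset == 1
        )
        ref = toy_genome["contigs"]["c1"][d1.genomic_position]  # reference strand
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        (av,) = assign_to_junctions(
            [VariantRecord("c1", d1.genomic_position, ref, alt)], index
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert av.coding_ref == comp[ref] and av.coding_alt == comp[alt]

    def test_ref_mismatch_raises(self, toy_genome):
        index = self._index(toy_genome)
        site = next(iter(index))
        wrong_ref = "A" if site.ref_base != "A" else "C"
        bad = VariantRecord(site.contig, site.genomic_position, wrong_ref, "G"
                            if wrong_ref != "G" else "T")
        if site.strand == "-":
            pass  # the coding-strand check still applies after complementing
        with pytest.raises(ValidationError):
            assign_to_junctions([bad], index)

    def test_matches_brute_force_lookup(self, random_transcripts):
        contigs, transcripts = random_transcripts(50, seed=9)
        sites = []
        for t in transcripts:
            sites += derive_junction_sites(trim_to_cds(t), contigs)
        index = collapse_nonredundant(sites)
        rng = np.random.default_rng(1)
        variants = []
        for _ in range(400):
            contig = f"rc{int(rng.integers(50))}"
            pos = int(rng.integers(len(contigs[contig])))
            ref = contigs[contig][pos]
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            variants.append(VariantRecord(contig, pos, ref, alt))
        assigned = assign_to_junctions(variants, index)
        got = {(av.key, av.site.key) for av in assigned}
        expected = set()
        for v in variants:
            for s in sites:
                if (s.contig, s.genomic_position) == (v.contig, v.position):
                    expected.add((v.key, s.key))
        assert got == expected


def _single_exon_transcript(cds_seq: str, strand="+", offset=10):
    """Transcript whose CDS is cds_seq embedded at `offset` in a padded contig."""
    from Bio.Seq import Seq

    genomic = cds_seq if strand == "+" else str(Seq(cds_seq).reverse_complement())
    contig = "A" * offset + genomic + "A" * 10
    t = TranscriptModel(
        "T", "G", "G", "c1", strand,
        exons=[(offset, offset + len(cds_seq))],
        cds=[(offset, offset + len(cds_seq))],
    )
    return t, {"c1": contig}


class TestCallConsequence:
    def test_third_base_G_to_A_of_GAG_is_silent(self):
        # codon GAG (Glu); G>A at its third base gives GAA (Glu): silent,
        # the classic c.G672A p.E224E pattern
        t, genome = _single_exon_transcript("ATGGAGTAA"[:6] + "GAG")
        # CDS = ATG GAG GAG; variant at last base (index 8)
        v = VariantRecord("c1", 10 + 8, "G", "A")
        assert call_consequence(v, t, genome) == "silent"

    def test_third_base_G_to_T_of_GAG_is_missense(self):
        # GAG -> GAT (Glu -> Asp): missense, the c.G672T p.E224D pattern
        t, genome = _single_exon_transcript("ATGGAGGAG")
        v = VariantRecord("c1", 10 + 8, "G", "T")
        assert call_consequence(v, t, genome) == "missense"

    def test_stop_gain_is_nonsense(self):
        t, genome = _single_exon_transcript("ATGTACGGG")
        # TAC -> TAA (Tyr -> stop)
        v = VariantRecord("c1", 10 + 5, "C", "A")
        assert call_consequence(v, t, genome) == "nonsense"

    def test_ref_stop_codon_is_other(self):
        t, genome = _single_exon_transcript("ATGTAAGGG")
        v = VariantRecord("c1", 10 + 5, "A", "G")
        assert call_consequence(v, t, genome) == "other"

    def test_minus_strand_silent(self):
        t, genome = _single_exon_transcript("ATGGAGGAG", strand="-")
        # coding G>A at the CDS-last base: on the minus strand that base sits
        # at the genomic start of the CDS span and reads C on the reference
        v = VariantRecord("c1", 10, "C", "T")
        assert call_consequence(v, t, genome) == "silent"

    def test_out_of_cds_raises(self):
        t, genome = _single_exon_transcript("ATGGAGGAG")
        with pytest.raises(OutOfCdsError):
            call_consequence(VariantRecord("c1", 2, "A", "G"), t, genome)

    def test_cds_not_multiple_of_three_raises(self):
        t, genome = _single_exon_transcript("ATGGAGGA")
        with pytest.raises(AnnotationError):
            call_consequence(VariantRecord("c1", 10, "A", "G"), t, genome)

    def test_agrees_with_whole_protein_oracle(self, random_transcripts):
        contigs, transcripts = random_transcripts(80, seed=21, micro_exons=False)
        usable = [t for t in transcripts if sum(e - s for s, e in t.cds) % 3 == 0]
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 1000:
            t = usable[int(rng.integers(len(usable)))]
            cds_positions = [p for s, e in t.cds for p in range(s, e)]
            pos = int(cds_positions[int(rng.integers(len(cds_positions)))])
            ref = contigs[t.contig][pos]
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            v = VariantRecord(t.contig, pos, ref, alt)
            assert call_consequence(v, t, contigs) == protein_consequence(
                t, contigs, pos, ref, alt
            )
            checked += 1

    def test_strand_reflection_leaves_consequence_unchanged(self, random_transcripts):
        contigs, transcripts = random_transcripts(30, seed=33, micro_exons=False)
        usable = [t for t in transcripts if sum(e - s for s, e in t.cds) % 3 == 0]
        rc_contigs, rc_transcripts = reflect_locus(contigs, {t.transcript_id: t for t in usable}.values())
        rc_by_id = {t.transcript_id: t for t in rc_transcripts}
        rng = np.random.default_rng(4)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(200):
            t = usable[int(rng.integers(len(usable)))]
            cds_positions = [p for s, e in t.cds for p in range(s, e)]
            pos = int(cds_positions[int(rng.integers(len(cds_positions)))])
            ref = contigs[t.contig][pos]
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            before = call_consequence(VariantRecord(t.contig, pos, ref, alt), t, contigs)
            L = len(contigs[t.contig])
            after = call_consequence(
                VariantRecord(t.contig, L - 1 - pos, comp[ref], comp[alt]),
                rc_by_id[t.transcript_id],
                rc_contigs,
            )
            assert before == after


class TestRecurrence:
    def test_rows_of_same_variant_sum(self):
        rows = [VariantRecord("c1", 5, "G", "T", occurrence=1) for _ in range(3)]
        table = recurrence(rows)
        assert table.counts[("c1", 5, "G", "T")] == 3
        assert table.fraction_at_least(2) == 1.0

    def test_all_unique_gives_zero_recurrent_fraction(self):
        rows = [VariantRecord("c1", i, "G", "T") for i in range(5)]
        table = recurrence(rows)
        assert table.fraction_at_least(2) == 0.0
        strata = table.strata()
        assert strata["1"] + strata[">=2"] == table.n_unique

    def test_geometric_closed_form(self):
        """With occurrence ~ zero-truncated geometric(q), P(occ >= 2) = 1 - q."""
        from spliceflank.simulate import RecurrenceModel

        q = 0.8
        model = RecurrenceModel(q=q, q_hot=None)
        rng = np.random.default_rng(0)
        rows = [
            VariantRecord("c1", i, "G", "T", occurrence=model.sample(rng, hot=True))
            for i in range(20000)
        ]
        frac = recurrence(rows).fraction_at_least(2)
        se = np.sqrt(q * (1 - q) / 20000)
        assert abs(frac - (1 - q)) < 3 * se


def test_consequence_partition(study_materials):
    """Every annotated variant has exactly one known consequence."""
    annotated = study_materials["annotated"]
    counts = {}
    for av in annotated:
        assert av.consequence in ("silent", "missense", "nonsense", "other")
        counts[av.consequence] = counts.get(av.consequence, 0) + 1
    assert sum(counts.values()) == len(annotated)
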