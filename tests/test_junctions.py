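"""Junction-site derivation: GTF parsing, canonical selection, UTR trimming,
strand-aware d1-d3/a1-a3 coordinates, non-redundant collapsing, BED round-trip."""

import pytest

from spliceflank.errors import CoordinateError, EmptyInputError, GtfParseError
from spliceflank.junctions import (
    CodingExon,
    TranscriptModel,
    collapse_nonredundant,
    derive_junction_sites,
    parse_gtf,
    read_sites_bed,
    select_canonical,
    sites_from_annotation,
    trim_to_cds,
    write_sites_bed,
)

from oracles import brute_force_site_keys, reflect_locus


def _write(tmp_path, text):
    path = tmp_path / "test.gtf"
    path.write_text(text)
    return str(path)


ATTRS = 'gene_id "G1"; gene_name "N1"; transcript_id "T1"; transcript_type "protein_coding";'


class TestParseGtf:
    def test_coordinates_converted_to_half_open(self, tmp_path):
        gtf = (
            f"c1\tsrc\texon\t101\t200\t.\t+\t.\t{ATTRS}\n"
            f"c1\tsrc\tCDS\t101\t200\t.\t+\t.\t{ATTRS}\n"
        )
        (model,) = parse_gtf(_write(tmp_path, gtf))
        assert model.exons == [(100, 200)]
        assert model.cds == [(100, 200)]

    def test_transcript_without_cds_dropped(self, tmp_path):
        gtf = f"c1\tsrc\texon\t101\t200\t.\t+\t.\t{ATTRS}\n"
        assert parse_gtf(_write(tmp_path, gtf)) == []

    def test_non_protein_coding_dropped(self, tmp_path):
        attrs = ATTRS.replace("protein_coding", "lncRNA")
        gtf = (
            f"c1\tsrc\texon\t101\t200\t.\t+\t.\t{attrs}\n"
            f"c1\tsrc\tCDS\t101\t200\t.\t+\t.\t{attrs}\n"
        )
        assert parse_gtf(_write(tmp_path, gtf)) == []

    def test_malformed_attributes_report_line_number(self, tmp_path):
        gtf = (
            f"c1\tsrc\texon\t101\t200\t.\t+\t.\t{ATTRS}\n"
            "c1\tsrc\texon\t1\t2\t.\t+\t.\tnonsense-attr-block\n"
        )
        with pytest.raises(GtfParseError, match="line 2"):
            parse_gtf(_write(tmp_path, gtf))

    def test_end_before_start_raises(self, tmp_path):
        gtf = f"c1\tsrc\texon\t200\t101\t.\t+\t.\t{ATTRS}\n"
        with pytest.raises(CoordinateError):
            parse_gtf(_write(tmp_path, gtf))

    def test_counts_match_generator_ground_truth(self, small_sim):
        transcripts = parse_gtf(str(small_sim["paths"]["gtf"]))
        canonical = [t for t in transcripts if t.canonical_flag]
        genes = small_sim["truth"].genes
        assert len(canonical) == len(genes)
        for t in canonical:
            assert len(t.exons) == genes[t.gene_id]["exon_count"]


class TestSelectCanonical:
    def _t(self, tid, gene="G1", cds_len=300, tagged=False):
        return TranscriptModel(
            transcript_id=tid,
            gene_id=gene,
            gene_name=gene,
            contig="c1",
            strand="+",
            exons=[(0, cds_len)],
            cds=[(0, cds_len)],
            canonical_flag=tagged,
        )

    def test_tagged_transcript_wins(self):
        chosen = select_canonical([self._t("A", cds_len=500), self._t("B", tagged=True)])
        assert [t.transcript_id for t in chosen] == ["B"]

    def test_fallback_longest_cds(self):
        chosen = select_canonical([self._t("A", cds_len=300), self._t("B", cds_len=450)])
        assert [t.transcript_id for t in chosen] == ["B"]

    def test_tie_breaks_lexicographically(self):
        chosen = select_canonical([self._t("B"), self._t("A")])
        assert [t.transcript_id for t in chosen] == ["A"]

    def test_one_per_gene_on_synthetic_annotation(self, small_sim):
        transcripts = parse_gtf(str(small_sim["paths"]["gtf"]))
        chosen = select_canonical(transcripts)
        assert len(chosen) == len(small_sim["truth"].genes)
        assert all(t.canonical_flag for t in chosen)


class TestTrimToCds:
    def test_intersection(self):
        t = TranscriptModel("T", "G", "G", "c1", "+", exons=[(100, 200)], cds=[(150, 200)])
        (exon,) = trim_to_cds(t)
        assert (exon.start, exon.end) == (150, 200)

    def test_pure_utr_exon_dropped(self):
        t = TranscriptModel(
            "T", "G", "G", "c1", "+",
            exons=[(0, 50), (100, 200)], cds=[(150, 200)],
        )
        exons = trim_to_cds(t)
        assert len(exons) == 1 and exons[0].start == 150

    def test_minus_strand_rank_follows_transcript_orientation(self):
        t = TranscriptModel(
            "T", "G", "G", "c1", "-",
            exons=[(0, 50), (100, 200)], cds=[(0, 50), (100, 200)],
        )
        exons = trim_to_cds(t)
        by_rank = {e.rank_in_transcript: (e.start, e.end) for e in exons}
        assert by_rank[1] == (100, 200)  # genomically-last exon is rank 1
        assert exons[0].is_first == (exons[0].rank_in_transcript == 1)


class TestDeriveSites:
    def test_plus_strand_internal_exon_positions(self):
        exon = CodingExon("T", "G", "c1", "+", 100, 200, 2, False, False)
        genome = {"c1": "A" * 300}
        sites = derive_junction_sites([exon], genome)
        positions = {(s.role, s.offset): s.genomic_position for s in sites}
        assert positions[("donor", 1)] == 199
        assert positions[("donor", 2)] == 198
        assert positions[("donor", 3)] == 197
        assert positions[("acceptor", 1)] == 100
        assert positions[("acceptor", 2)] == 101
        assert positions[("acceptor", 3)] == 102

    def test_minus_strand_positions_and_refbase(self):
        exon = CodingExon("T", "G", "c1", "-", 100, 200, 2, False, False)
        genome = {"c1": "A" * 100 + "C" + "A" * 199}  # C at position 100
        sites = derive_junction_sites([exon], genome)
        positions = {(s.role, s.offset): s.genomic_position for s in sites}
        assert positions[("donor", 1)] == 100
        assert positions[("donor", 3)] == 102
        assert positions[("acceptor", 1)] == 199
        assert positions[("acceptor", 3)] == 197
        d1 = next(s for s in sites if s.role == "donor" and s.offset == 1)
        assert d1.ref_base == "G"  # reverse complement of the reference C

    def test_site_counts_for_n_exons(self):
        genome = {"c1": "A" * 2000}
        exons = [
            CodingExon("T", "G", "c1", "+", 100 * i, 100 * i + 50, i + 1, i == 0, i == 4)
            for i in range(5)
        ]
        sites = derive_junction_sites(exons, genome)
        donors = [s for s in sites if s.role == "donor"]
        acceptors = [s for s in sites if s.role == "acceptor"]
        assert len(donors) == len(acceptors) == 3 * 4  # 3(n-1) each

    def test_micro_exon_clamps_offsets(self):
        exon = CodingExon("T", "G", "c1", "+", 100, 102, 2, False, False)
        sites = derive_junction_sites([exon], {"c1": "A" * 200})
        assert {(s.role, s.offset) for s in sites} == {
            ("donor", 1), ("donor", 2), ("acceptor", 1), ("acceptor", 2),
        }

    def test_single_exon_transcript_emits_nothing(self):
        exon = CodingExon("T", "G", "c1", "+", 100, 200, 1, True, True)
        assert derive_junction_sites([exon], {"c1": "A" * 300}) == []

    def test_out_of_bounds_site_raises(self):
        exon = CodingExon("T", "G", "c1", "+", 100, 200, 1, True, False)
        with pytest.raises(CoordinateError):
            derive_junction_sites([exon], {"c1": "A" * 150})


class TestCollapse:
    def test_shared_exon_end_deduplicates(self, toy_genome):
        t = toy_genome["plus"]
        exons = trim_to_cds(t) + trim_to_cds(t)
        sites = derive_junction_sites(exons, toy_genome["contigs"])
        index = collapse_nonredundant(sites)
        assert len(index) == 6  # 3 donor + 3 acceptor, each once

    def test_gene_lists_unioned(self):
        genome = {"c1": "A" * 300}
        e1 = CodingExon("T1", "G1", "c1", "+", 100, 200, 1, True, False)
        e2 = CodingExon("T2", "G2", "c1", "+", 100, 200, 1, True, False)
        index = collapse_nonredundant(derive_junction_sites([e1, e2], genome))
        assert all(site.gene_ids == ("G1", "G2") for site in index)

    def test_empty_input_gives_empty_index(self):
        assert len(collapse_nonredundant([])) == 0

    def test_matches_brute_force_on_random_transcripts(self, random_transcripts):
        contigs, transcripts = random_transcripts(200, seed=3)
        expected = set()
        for t in transcripts:
            expected |= brute_force_site_keys(t, contigs)
        got = set()
        for t in transcripts:
            for s in derive_junction_sites(trim_to_cds(t), contigs):
                got.add((s.contig, s.genomic_position, s.strand, s.role, s.offset, s.ref_base))
        assert got == expected


class TestStrandSymmetry:
    def test_reflection_preserves_sites_under_transform(self, random_transcripts):
        contigs, transcripts = random_transcripts(60, seed=5)
        original = set()
        for t in transcripts:
            for s in derive_junction_sites(trim_to_cds(t), contigs):
                original.add((s.contig, s.genomic_position, s.strand, s.role, s.offset, s.ref_base))
        rc_contigs, rc_transcripts = reflect_locus(contigs, transcripts)
        reflected = set()
        for t in rc_transcripts:
            for s in derive_junction_sites(trim_to_cds(t), rc_contigs):
                L = len(contigs[s.contig])
                strand = "-" if s.strand == "+" else "+"
                reflected.add((s.contig, L - 1 - s.genomic_position, strand, s.role, s.offset, s.ref_base))
        assert reflected == original


class TestBedIO:
    def test_round_trip_reconstructs_index(self, toy_genome, tmp_path):
        sites = []
        for key in ("plus", "minus"):
            sites += derive_junction_sites(
                trim_to_cds(toy_genome[key]), toy_genome["contigs"]
            )
        index = collapse_nonredundant(sites)
        path = tmp_path / "sites.bed"
        write_sites_bed(index, str(path))
        recovered = read_sites_bed(str(path))
        assert set(recovered.sites) == set(index.sites)
        for key, site in index.sites.items():
            assert recovered.sites[key].ref_base == site.ref_base
            assert recovered.sites[key].gene_ids == site.gene_ids
        first = path.read_text().splitlines()[0].split("\t")
        assert int(first[2]) == int(first[1]) + 1  # BED half-open 1 bp intervals

    def test_empty_index_refuses_to_write(self, tmp_path):
        with pytest.raises(EmptyInputError):
            write_sites_bed(collapse_nonredundant([]), str(tmp_path / "x.bed"))


def test_roundtrip_recovers_generator_site_map(small_sim):
    """Sites derived from the emitted GTF equal the generator's internal map."""
    transcripts = parse_gtf(str(small_sim["paths"]["gtf"]))
    index = sites_from_annotation(transcripts, small_sim["genome"])
    derived = {
        (s.contig, s.genomic_position, s.strand, s.role, s.offset, s.ref_base)
        for s in index
    }
    planted = {
        (s["contig"], s["pos"], s["strand"], s["role"], s["offset"], s["ref_base"])
        for s in small_sim["truth"].sites
    }
    assert derived == planted
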