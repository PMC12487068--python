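import pytest

from mirabind.sequence_io import (
    CdsFeature,
    PipelineConfig,
    SeqRecord,
    call_orfs,
    check_samples_in_metadata,
    load_config,
    read_fasta,
    read_gff_cds,
    read_metadata,
    read_mirna_fasta,
    read_samples,
    reverse_complement,
    save_config,
    species_from_taxonomy,
    write_fasta,
)


class TestFasta:
    def test_multiline_record_concatenated_and_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGT\nACGT\n>m1 some description\nuggaau\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["c1", "m1"]
        assert recs[0].seq == "ACGTACGT"
        assert recs[1].seq == "UGGAAU"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(p)

    def test_empty_file_and_illegal_character(self, tmp_path):
        empty = tmp_path / "e.fa"
        empty.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_fasta(empty)
        bad = tmp_path / "b.fa"
        bad.write_text(">x\nACXT\n")
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(bad)

    def test_roundtrip_byte_identity_of_sequences(self, tmp_path):
        recs = [SeqRecord(id="g1", seq="ACGT" * 40), SeqRecord(id="g2", seq="TTTTNNAA")]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]

    def test_mirna_normalization_and_bounds(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">mir1\nTGAGGTAGTAGGTTGTATAGTT\n")
        (rec,) = read_mirna_fasta(p)
        assert rec.seq == "UGAGGUAGUAGGUUGUAUAGUU"
        assert rec.length == 22
        short = tmp_path / "s.fa"
        short.write_text(">tiny\nACGU\n")
        with pytest.raises(ValueError, match="length"):
            read_mirna_fasta(short)


class TestGff:
    GFF = (
        "##gff-version 3\n"
        "c1\tx\tCDS\t101\t400\t.\t+\t0\tID=g1;product=hypothetical\n"
        "c1\tx\ttRNA\t500\t600\t.\t+\t0\tID=t1\n"
        "c1\tx\tCDS\t201\t500\t.\t-\t0\tID=g2;gene=abcZ\n"
    )

    def test_coordinates_converted_and_non_cds_skipped(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(self.GFF)
        feats = read_gff_cds(p, "G1")
        assert [f.cds_id for f in feats] == ["g1", "g2"]
        assert (feats[0].start, feats[0].end, feats[0].strand) == (100, 400, "+")
        assert (feats[1].start, feats[1].end, feats[1].strand) == (200, 500, "-")
        assert feats[0].product == "hypothetical"
        assert feats[1].gene_name == "abcZ"

    def test_malformed_rows_report_line_numbers(self, tmp_path):
        p = tmp_path / "bad.gff"
        p.write_text("c1\tx\tCDS\t1\t10\n")
        with pytest.raises(ValueError, match=":1:"):
            read_gff_cds(p, "G1")
        p.write_text("c1\tx\tCDS\t50\t10\t.\t+\t0\tID=g\n")
        with pytest.raises(ValueError, match="end"):
            read_gff_cds(p, "G1")

    def test_unknown_contig_flagged_but_kept(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(self.GFF)
        feats = read_gff_cds(p, "G1", known_contigs={"other"})
        assert all(not f.on_known_contig for f in feats)
        assert len(feats) == 2


class TestOrfCaller:
    def test_simple_plus_strand_orf(self):
        rec = SeqRecord(id="c", seq="AAA" + "ATG" + "AAA" + "TAA" + "AAA")
        orfs = call_orfs(rec, min_len=9)
        assert len(orfs) == 1
        (orf,) = orfs
        assert (orf.start, orf.end, orf.strand) == (3, 12, "+")
        assert rec.seq[orf.start : orf.end] == "ATGAAATAA"

    def test_reverse_complement_symmetry(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        rec = SeqRecord(id="c", seq=seq)
        rc = SeqRecord(id="c", seq=reverse_complement(seq))
        fwd = {(o.start, o.end, o.strand) for o in call_orfs(rec, min_len=60)}
        n = len(seq)
        flipped = {
            (n - o.end, n - o.start, "+" if o.strand == "-" else "-")
            for o in call_orfs(rc, min_len=60)
        }
        assert fwd == flipped and fwd  # non-trivial ORF set mirrors exactly

    def test_start_without_stop_yields_nothing(self):
        rec = SeqRecord(id="c", seq="ATGAAAAAAAAAAAA")
        assert call_orfs(rec, min_len=9) == []


class TestTables:
    def test_metadata_groups_and_sample_check(self, tmp_path):
        meta = tmp_path / "m.tsv"
        meta.write_text(
            "genome_id\tgroup\ttaxonomy\n"
            "g1\trumen\td__Bacteria;g__Prevotella;s__Prevotella ruminicola\n"
            "g2\tfeces\td__Bacteria;g__Escherichia;s__Escherichia coli\n"
        )
        df = read_metadata(meta)
        assert set(df["group"]) == {"rumen", "feces"}
        samples = tmp_path / "s.txt"
        samples.write_text("g1\ng2\ng3\n")
        with pytest.raises(ValueError, match="g3"):
            check_samples_in_metadata(read_samples(samples), df)

    def test_duplicate_genome_id_rejected(self, tmp_path):
        meta = tmp_path / "m.tsv"
        meta.write_text("genome_id\tgroup\ttaxonomy\ng1\ta\t\ng1\tb\t\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_metadata(meta)

    @pytest.mark.parametrize(
        "taxonomy,species",
        [
            ("d__Bacteria;p__X;s__Escherichia coli", "Escherichia coli"),
            ("Bacteria;Proteobacteria;Escherichia coli", "Escherichia coli"),
            ("d__Bacteria;s__", ""),
        ],
    )
    def test_species_extraction(self, taxonomy, species):
        assert species_from_taxonomy(taxonomy) == species


class TestConfig:
    def test_yaml_roundtrip_and_unknown_key(self, tmp_path):
        cfg = PipelineConfig(genome_dir="g", rng_seed=11, mfe_cutoff=-18.5)
        p = tmp_path / "c.yaml"
        save_config(cfg, p)
        assert load_config(p) == cfg
        p.write_text("genome_dir: g\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_config(p)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(pval_cutoff=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(mfe_cutoff=5.0)
        with pytest.raises(ValueError):
            CdsFeature(contig="c", start=10, end=5, strand="+", cds_id="x")
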