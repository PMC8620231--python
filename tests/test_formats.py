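"""GTF/GFF/config parsing and writing."""

import random

import pytest

from txselect import formats
from txselect.formats import ConfigError, ParseError
from txselect.scoring import FeatureKey, Hyperparameters
from txselect.selection import GeneCluster

from conftest import make_tx


def gtf_row(seqname, feature, start, end, strand, tid, gid="g1", frame="0", score="."):
    return (
        f'{seqname}\tsrc\t{feature}\t{start}\t{end}\t{score}\t{strand}\t{frame}\t'
        f'gene_id "{gid}"; transcript_id "{tid}";\n'
    )


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

class TestParsePredictions:
    def test_two_transcripts_three_cds_each(self, tmp_path):
        rows = []
        # deliberately unsorted CDS rows
        for tid, offs in (("t1", 0), ("t2", 5000)):
            for s, e in [(300, 400), (100, 200), (500, 580)]:
                rows.append(gtf_row("chr1", "CDS", s + offs, e + offs, "+", tid))
        path = tmp_path / "p.gtf"
        path.write_text("".join(rows))
        txs = formats.parse_predictions(path)
        assert len(txs) == 2
        assert txs[0].cds == ((100, 200), (300, 400), (500, 580))
        assert txs[0].strand == "+"

    def test_file_index_prefix_keeps_colliding_ids_distinct(self, tmp_path):
        for name, index in (("a.gtf", 1), ("b.gtf", 2)):
            (tmp_path / name).write_text(gtf_row("chr1", "CDS", 100, 200, "+", "t1"))
        txs = formats.parse_predictions(tmp_path / "a.gtf", file_index=1)
        txs += formats.parse_predictions(tmp_path / "b.gtf", file_index=2)
        assert {t.tx_id for t in txs} == {"1_t1", "2_t1"}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert formats.parse_predictions(path) == []

    def test_transcript_without_cds_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "p.gtf"
        path.write_text(
            gtf_row("chr1", "exon", 100, 200, "+", "noCDS")
            + gtf_row("chr1", "CDS", 100, 200, "+", "ok")
        )
        with caplog.at_level("WARNING", logger="txselect"):
            txs = formats.parse_predictions(path)
        assert [t.tx_id for t in txs] == ["ok"]
        assert "noCDS" in caplog.text

    def test_explicit_codon_rows_are_kept(self, tmp_path):
        path = tmp_path / "p.gtf"
        path.write_text(
            gtf_row("chr1", "CDS", 100, 400, "+", "t1")
            + gtf_row("chr1", "start_codon", 100, 102, "+", "t1")
            + gtf_row("chr1", "stop_codon", 401, 403, "+", "t1")
        )
        (tx,) = formats.parse_predictions(path)
        assert tx.start_codon == (100, 102)
        assert tx.stop_codon == (401, 403)

    @pytest.mark.parametrize(
        "rows, match",
        [
            (gtf_row("chr1", "CDS", 100, 200, "+", "t1")
             + gtf_row("chr1", "CDS", 300, 400, "-", "t1"), "t1"),
            (gtf_row("chr1", "CDS", 100, 200, "+", "t1")
             + gtf_row("chr2", "CDS", 300, 400, "+", "t1"), "t1"),
            ("chr1\tsrc\tCDS\t100\n", ":1"),
            (gtf_row("chr1", "CDS", 100, 200, ".", "t1"), "strand"),
            (gtf_row("chr1", "CDS", 200, 100, "+", "t1"), "start"),
            ('chr1\tsrc\tCDS\t100\t200\t.\t+\t0\tfoo "bar";\n', "transcript_id"),
        ],
    )
    def test_malformed_rows_raise_with_context(self, tmp_path, rows, match):
        path = tmp_path / "bad.gtf"
        path.write_text(rows)
        with pytest.raises(ParseError, match=match):
            formats.parse_predictions(path)


# ---------------------------------------------------------------------------
# hints
# ---------------------------------------------------------------------------

def hint_row(feature, start, end, attrs, seqname="chr1", strand="+"):
    return f"{seqname}\thints\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


class TestParseHints:
    def test_mult_and_src_attributes(self, tmp_path):
        path = tmp_path / "h.gff"
        path.write_text(hint_row("intron", 201, 299, "mult=5;src=P"))
        hints = formats.parse_hints([path])
        key = FeatureKey("chr1", 201, 299, "intron", "+")
        assert hints.support_of(key) == {"P": 5}
        assert hints.sources == {"P"}

    def test_absent_mult_means_one(self, tmp_path):
        path = tmp_path / "h.gff"
        path.write_text(hint_row("intron", 201, 299, "src=E"))
        hints = formats.parse_hints([path])
        assert hints.support_of(FeatureKey("chr1", 201, 299, "intron", "+")) == {"E": 1}

    def test_duplicate_rows_sum_multiplicities(self, tmp_path):
        path = tmp_path / "h.gff"
        path.write_text(
            hint_row("intron", 201, 299, "mult=2;src=E")
            + hint_row("intron", 201, 299, "mult=3;src=E")
        )
        hints = formats.parse_hints([path])
        assert hints.support_of(FeatureKey("chr1", 201, 299, "intron", "+")) == {"E": 5}
        assert len(hints) == 1

    def test_codon_spelling_aliases(self, tmp_path):
        path = tmp_path / "h.gff"
        path.write_text(
            hint_row("start_codon", 100, 102, "src=P") + hint_row("stop", 398, 400, "src=P")
        )
        hints = formats.parse_hints([path])
        assert hints.supports(FeatureKey("chr1", 100, 102, "start", "+"))
        assert hints.supports(FeatureKey("chr1", 398, 400, "stop", "+"))

    def test_missing_src_is_an_error(self, tmp_path):
        path = tmp_path / "h.gff"
        path.write_text(hint_row("intron", 201, 299, "mult=5"))
        with pytest.raises(ParseError, match="src"):
            formats.parse_hints([path])

    def test_unknown_feature_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "h.gff"
        path.write_text(
            hint_row("exonpart", 150, 180, "src=E") + hint_row("intron", 201, 299, "src=E")
        )
        with caplog.at_level("WARNING", logger="txselect"):
            hints = formats.parse_hints([path])
        assert len(hints) == 1
        assert "exonpart" in caplog.text

    def test_codon_hint_must_span_three_nt(self, tmp_path):
        path = tmp_path / "h.gff"
        path.write_text(hint_row("start", 100, 104, "src=P"))
        with pytest.raises(ParseError, match="3 nt"):
            formats.parse_hints([path])

    def test_multiplicity_conserved_over_random_rows(self, tmp_path):
        rng = random.Random(7)
        total = 0
        rows = []
        for _ in range(100):
            start = rng.randrange(1, 10_000)
            end = start + rng.randrange(30, 500)
            mult = rng.randint(1, 50)
            src = rng.choice("PECM")
            total += mult
            rows.append(hint_row("intron", start, end, f"mult={mult};src={src}"))
        rng.shuffle(rows)
        path = tmp_path / "h.gff"
        path.write_text("".join(rows))
        assert formats.parse_hints([path]).total_multiplicity() == total


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class TestParseConfig:
    def test_empty_file_yields_defaults(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("")
        p = formats.parse_config(path)
        assert p.weights == {"P": 0.1, "E": 10.0, "C": 5.0, "M": 1.0}
        assert (p.e1, p.e2, p.e3, p.e4) == (0.0, 0.5, 25.0, 10.0)
        assert (p.intron_support, p.startstop_support) == (0.75, 1.0)

    def test_partial_override(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("# comment\ne_3 50\nw_R 2.5\n")
        p = formats.parse_config(path)
        assert p.e3 == 50.0
        assert p.weights["R"] == 2.5
        assert p.e2 == 0.5 and p.weights["E"] == 10.0

    @pytest.mark.parametrize(
        "text, match",
        [("w_P abc\n", "abc"), ("epsilon_9 1\n", "unknown"), ("e_1\n", "name value")],
    )
    def test_bad_entries(self, tmp_path, text, match):
        path = tmp_path / "cfg"
        path.write_text(text)
        with pytest.raises(ConfigError, match=match):
            formats.parse_config(path)

    def test_invalid_threshold_rejected(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("e_1 1.5\n")
        with pytest.raises(ConfigError):
            formats.parse_config(path)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def cluster(gene_id, *txs):
    return GeneCluster(gene_id, txs[0].seqname, txs[0].strand, list(txs))


class TestWriteAnnotation:
    def test_isoforms_share_gene_id(self, tmp_path):
        t1 = make_tx("a", cds=((100, 200), (300, 400)))
        t2 = make_tx("b", cds=((100, 200), (300, 450)))
        out = tmp_path / "out.gtf"
        formats.write_annotation([cluster("g1", t1, t2)], out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        gids = {l.split("\t")[8].split('"')[1] for l in lines}
        tids = {l.split('transcript_id "')[1].split('"')[0] for l in lines}
        assert gids == {"g1"} and tids == {"a", "b"}

    def test_output_is_pure_function_of_content(self, tmp_path):
        a = make_tx("a", cds=((100, 200),))
        b = make_tx("b", cds=((5000, 5200),))
        one = formats.annotation_to_text([cluster("gx", a), cluster("gy", b)])
        two = formats.annotation_to_text([cluster("gy", b), cluster("gx", a)])
        assert one == two
        # genes are renumbered in coordinate order
        assert one.index('"g1"') < one.index('"g2"')

    def test_empty_selection_writes_header_only(self, tmp_path):
        out = tmp_path / "out.gtf"
        formats.write_annotation([], out)
        assert out.read_text() == formats.OUTPUT_HEADER + "\n"
        assert formats.parse_predictions(out) == []

    def test_round_trip_preserves_cds_strand_frame(self, tmp_path):
        rng = random.Random(11)
        txs = []
        for i in range(20):
            n = rng.randint(1, 5)
            pos = rng.randrange(1, 50_000)
            cds = []
            for _ in range(n):
                end = pos + rng.randrange(10, 400)
                cds.append((pos, end))
                pos = end + rng.randrange(2, 300)
            txs.append(
                make_tx(f"t{i}", seqname=f"chr{i % 3}", strand=rng.choice("+-"), cds=tuple(cds))
            )
        out = tmp_path / "out.gtf"
        formats.write_annotation([cluster(f"g{i}", t) for i, t in enumerate(txs)], out)
        back = {t.tx_id: t for t in formats.parse_predictions(out)}
        assert len(back) == len(txs)
        from txselect.scoring import cds_phases

        for t in txs:
            got = back[t.tx_id]
            assert got.cds == t.cds
            assert got.strand == t.strand
            assert got.frames == cds_phases(t.cds, t.strand)
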