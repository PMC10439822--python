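import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimgo import formats_io as fio
from tests.conftest import make_hit


# ---------------------------------------------------------------------------
# FASTA

class TestReadFasta:
    def test_two_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">q1 desc here\nACGT\n>q2\nTTTT\n")
        records = fio.read_fasta(p)
        assert [r.id for r in records] == ["q1", "q2"]
        assert records[0].description == "desc here"
        assert records[0].sequence == "ACGT"
        assert records[1].description == ""

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">q1\nACGT\n>q1\nTTTT\n")
        with pytest.raises(fio.FormatError, match="q1"):
            fio.read_fasta(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(fio.FormatError):
            fio.read_fasta(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fio.read_fasta(tmp_path / "nope.fasta")

    def test_generated_fixture_count(self, tmp_path):
        records = [fio.SequenceRecord(f"q{i}", "", "ACGT" * 10)
                   for i in range(50)]
        p = tmp_path / "gen.fasta"
        fio.write_fasta(records, p)
        assert len(fio.read_fasta(p)) == 50


# ---------------------------------------------------------------------------
# tabular hits

class TestTabularHits:
    def test_parse_single_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t97.5\t120\t3\t0\t1\t360\t1\t120\t1e-50\t230\n")
        (hit,) = fio.read_tabular_hits(p)
        assert hit.query_id == "q1"
        assert hit.subject_id == "s1"
        assert hit.percent_identity == 97.5
        assert hit.alignment_length == 120
        assert hit.evalue == 1e-50
        assert hit.bitscore == 230.0

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert fio.read_tabular_hits(p) == []

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t97.5\n")
        with pytest.raises(fio.FormatError, match=":1"):
            fio.read_tabular_hits(p)

    def test_non_numeric_field_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        good = "q1\ts1\t97.5\t120\t3\t0\t1\t360\t1\t120\t1e-50\t230\n"
        bad = "q2\ts1\tXX\t120\t3\t0\t1\t360\t1\t120\t1e-50\t230\n"
        p.write_text(good + bad)
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_tabular_hits(p)

    def test_order_preserved(self, tmp_path):
        rng = random.Random(5)
        hits = [make_hit(query=f"q{rng.randrange(10)}", subject=f"s{i}")
                for i in range(100)]
        p = tmp_path / "hits.tsv"
        fio.write_tabular_hits(hits, p)
        back = fio.read_tabular_hits(p)
        assert [(h.query_id, h.subject_id) for h in back] == \
               [(h.query_id, h.subject_id) for h in hits]

    def test_round_trip_byte_identical(self, tmp_path):
        rng = random.Random(7)
        hits = [make_hit(query=f"q{i}", subject=f"s{i}",
                         evalue=rng.choice([0.0, 1e-5, 3.2e-12, 1e-180]),
                         bitscore=rng.uniform(30, 900),
                         pident=rng.uniform(10, 100))
                for i in range(500)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        fio.write_tabular_hits(hits, p1)
        fio.write_tabular_hits(fio.read_tabular_hits(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            make_hit(pident=150.0)
        with pytest.raises(ValueError):
            make_hit(evalue=-1.0)
        with pytest.raises(ValueError):
            make_hit(length=0)


# ---------------------------------------------------------------------------
# slim mappings

class TestSlimMapping:
    def _write(self, tmp_path, lines, name="map.tsv"):
        p = tmp_path / name
        p.write_text("".join(line + "\n" for line in lines))
        return p

    def test_canonical_aggregates_sets(self, tmp_path):
        p = self._write(tmp_path, ["g1\tbinding", "g1\ttransport",
                                   "g2\tbinding"])
        m = fio.read_slim_mapping(p)
        assert m.entries == {"g1": {"binding", "transport"},
                             "g2": {"binding"}}

    def test_exclusion_drops_pairs_and_empty_keys(self, tmp_path):
        p = self._write(tmp_path, ["g1\tbinding", "g1\ttransport",
                                   "g2\tbinding", "g3\ttransport"])
        m = fio.read_slim_mapping(p, excluded_categories={"transport"})
        assert m.entries == {"g1": {"binding"}, "g2": {"binding"}}
        assert "g3" not in m.entries

    def test_tair_dialect_matches_canonical(self, tmp_path):
        entries = {"AT1G01010.1": {"binding"}, "AT1G01020.1": {"transport"}}
        canonical = self._write(
            tmp_path,
            [f"{k}\t{c}" for k in sorted(entries) for c in sorted(entries[k])],
            "canonical.tsv")
        tair_lines = ["!comment line", "! another comment"]
        for k in sorted(entries):
            for c in sorted(entries[k]):
                tair_lines.append(f"{k}\textra\tignored\t{c}\tGO:0000001")
        tair = self._write(tmp_path, tair_lines, "tair.tsv")
        m1 = fio.read_slim_mapping(canonical)
        m2 = fio.read_slim_mapping(tair, dialect="tair", key_column=0,
                                   term_column=3)
        assert m1.entries == m2.entries

    def test_unknown_dialect(self, tmp_path):
        p = self._write(tmp_path, ["g1\tbinding"])
        with pytest.raises(ValueError, match="dialect"):
            fio.read_slim_mapping(p, dialect="gaf")

    def test_malformed_line_reports_number(self, tmp_path):
        p = self._write(tmp_path, ["g1\tbinding", "justonecolumn"])
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_slim_mapping(p)

    def test_round_trip(self, tmp_path):
        entries = {f"g{i}": frozenset({"binding", f"cat{i % 3}"})
                   for i in range(20)}
        m = fio.SlimMapping(entries)
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        fio.write_slim_mapping(m, p1)
        fio.write_slim_mapping(fio.read_slim_mapping(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_value_set_invariant(self):
        with pytest.raises(ValueError):
            fio.SlimMapping({"g1": frozenset()})


@given(st.sets(st.sampled_from(["a", "b", "c", "d"]), max_size=3))
@settings(max_examples=25, deadline=None)
def test_mapping_exclusion_shrinks_only(excluded):
    import tempfile

    lines = ["g1\ta", "g1\tb", "g2\tc", "g3\td", "g3\ta"]
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write("".join(l + "\n" for l in lines))
        path = fh.name
    try:
        full = fio.read_slim_mapping(path)
        reduced = fio.read_slim_mapping(path, excluded_categories=excluded)
        assert len(reduced.entries) <= len(full.entries)
        for cats in reduced.entries.values():
            assert not (cats & excluded)
    finally:
        import os
        os.unlink(path)


# ---------------------------------------------------------------------------
# summary tables

class TestSummaryTables:
    def test_round_trip_small(self, tmp_path):
        t = fio.SlimCountTable("demo", "gene", "raw",
                               {"binding": 3, "transport": 1},
                               n_input_sequences=10, n_with_best_hit=5,
                               n_annotated=4)
        p = tmp_path / "t.tsv"
        fio.write_table(t, p)
        back = fio.read_table(p)
        assert back == t

    def test_empty_table_round_trip(self, tmp_path):
        t = fio.SlimCountTable("demo", "locus", "frequency", {},
                               n_input_sequences=3)
        p = tmp_path / "t.tsv"
        fio.write_table(t, p)
        back = fio.read_table(p)
        assert back.values == {}
        assert back.level == "locus"

    def test_frequency_round_trip_tolerance(self, tmp_path):
        rng = random.Random(11)
        raw = {f"cat{i:02d}": rng.randint(1, 500) for i in range(36)}
        total = sum(raw.values())
        t = fio.SlimCountTable("demo", "gene", "frequency",
                               {c: v / total for c, v in raw.items()},
                               n_input_sequences=total)
        p = tmp_path / "t.tsv"
        fio.write_table(t, p)
        back = fio.read_table(p)
        for c in raw:
            assert abs(back.values[c] - t.values[c]) < 1e-12

    def test_missing_header(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("binding\t3\n")
        with pytest.raises(fio.FormatError, match="header"):
            fio.read_table(p)

    def test_non_numeric_cell(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("GO_slim_category\tdemo\nbinding\tmany\n")
        with pytest.raises(fio.FormatError, match="non-numeric"):
            fio.read_table(p)
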