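import math

import pytest
from hypothesis import given, strategies as st

from matrisomekit.errors import TableFormatError
from matrisomekit.tabular_io import (
    OmicsTable,
    coerce_numeric_columns,
    parse_numeric,
    read_skyline,
    read_table,
    sniff_number_format,
    write_csv,
)
from conftest import make_table


class TestReadTable:
    def test_comma_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b,c\n1,2,3\n4,5,6\n7,8,9\n10,11,12\n")
        t = read_table(p)
        assert t.headers == ["a", "b", "c"]
        assert t.n_rows == 4
        assert t.column("b") == ["2", "5", "8", "11"]

    def test_duplicate_header_names_position(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,a,b\n1,2,3\n")
        with pytest.raises(TableFormatError, match="position 2"):
            read_table(p)

    def test_empty_header_refused(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,,b\n1,2,3\n")
        with pytest.raises(TableFormatError, match="empty header"):
            read_table(p)

    def test_tab_delimited_txt_sniffed_like_tsv(self, tmp_path):
        content = "g\tx\ty\nFN1\t1\t2\nCOL1A1\t3\t4\n"
        p_txt = tmp_path / "t.txt"
        p_tsv = tmp_path / "t.tsv"
        p_txt.write_text(content)
        p_tsv.write_text(content)
        t_txt, t_tsv = read_table(p_txt), read_table(p_tsv)
        assert t_txt.headers == t_tsv.headers == ["g", "x", "y"]
        assert t_txt.df.equals(t_tsv.df)
        assert t_txt.provenance["delimiter"] == "\t"

    def test_zero_data_rows_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b\n")
        with pytest.warns(UserWarning, match="zero data rows"):
            t = read_table(p)
        assert t.n_rows == 0 and t.headers == ["a", "b"]

    def test_short_rows_padded_with_empty_cells(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b,c\n1,2\n")
        t = read_table(p)
        assert t.column("c") == [""]

    def test_undecodable_bytes_raise(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_bytes(b"a,b\n\xff\xfe,1\n")
        with pytest.raises(UnicodeDecodeError):
            read_table(p)


class TestNumberSniffer:
    @pytest.mark.parametrize(
        ("values", "decimal", "percent", "coercible"),
        [
            (["12.5", "3.0", "0.7"], "dot", False, True),
            (["1", "2", "3"], "dot", False, True),
            (["1e3", "-2.5E-1", "4"], "dot", False, True),
            (["3,14", "2,5"], "comma", False, True),
            (["99%", "100%"], None, True, False),
            (["1,204", "12,500"], None, False, False),  # ambiguous thousands grouping
            (["5", "high", "2"], None, False, False),   # below 90% agreement
            (["", "", ""], None, False, False),
        ],
    )
    def test_rules(self, values, decimal, percent, coercible):
        fmt = sniff_number_format(values)
        assert (fmt.decimal, fmt.percent, fmt.coercible) == (decimal, percent, coercible)

    def test_comma_decimal_parses_to_dot_value(self):
        fmt = sniff_number_format(["3,14", "2,5"])
        parsed = parse_numeric(["3,14", "2,5"], fmt)
        assert math.isclose(parsed.iloc[0], 3.14)
        assert math.isclose(parsed.iloc[1], 2.5)

    def test_empty_cells_parse_to_missing(self):
        fmt = sniff_number_format(["1", "", "3"])
        parsed = parse_numeric(["1", "", "3"], fmt)
        assert parsed.isna().tolist() == [False, True, False]

    @given(st.lists(st.integers(0, 100).map(lambda n: f"{n}%"), min_size=1, max_size=20))
    def test_percent_columns_never_coercible(self, values):
        assert not sniff_number_format(values).coercible

    def test_sporadic_footnote_cell_tolerated(self):
        values = ["1.5"] * 19 + ["n.d."]
        assert sniff_number_format(values).coercible


class TestClassification:
    def test_proteomics_style_columns(self):
        t = make_table({
            "Protein": ["FN1", "COL1A1", "ALB"],
            "Spectra": ["10", "3", "7"],
            "Mass": ["262.6", "138.9", "69.3"],
            "Prob": ["100%", "99%", "95%"],
        })
        cls = coerce_numeric_columns(t)
        assert cls.kinds["Spectra"] == "coercible"
        assert cls.kinds["Mass"] == "coercible"
        assert cls.kinds["Prob"] == "non_coercible"
        assert cls.kinds["Protein"] == "identifier_like"

    def test_invariant_under_row_permutation_and_blank_padding(self):
        base = {"x": ["1", "2", "3"], "y": ["a", "b", "c"]}
        t1 = make_table(base)
        t2 = make_table({"x": ["3", "1", "2", ""], "y": ["c", "a", "b", ""]})
        k1 = coerce_numeric_columns(t1).kinds
        k2 = coerce_numeric_columns(t2).kinds
        assert k1 == k2


class TestSkyline:
    DOC = """<?xml version="1.0"?>
<srm_settings>
  <protein name="P02452" accession="P02452">
    <peptide sequence="AAA"/><peptide sequence="BBB"/><peptide sequence="CCC"/>
  </protein>
  <protein accession="Q9XYZ1">
    <peptide sequence="DDD"/>
  </protein>
</srm_settings>
"""

    def test_protein_and_peptide_counts(self, tmp_path):
        p = tmp_path / "d.sky"
        p.write_text(self.DOC)
        t = read_skyline(p)
        assert t.headers == ["Protein", "Peptides"]
        assert list(zip(t.column("Protein"), t.column("Peptides"))) == [
            ("P02452", "3"), ("Q9XYZ1", "1")]

    def test_label_attribute_fallback_and_zero_peptides(self, tmp_path):
        p = tmp_path / "d.sky"
        p.write_text('<doc><protein label="OnlyLabel"></protein></doc>')
        t = read_skyline(p)
        assert t.column("Protein") == ["OnlyLabel"]
        assert t.column("Peptides") == ["0"]

    def test_non_xml_raises_format_error(self, tmp_path):
        p = tmp_path / "d.sky"
        p.write_text("this,is,csv\n1,2,3\n")
        with pytest.raises(TableFormatError, match="XML"):
            read_skyline(p)

    def test_no_proteins_warns(self, tmp_path):
        p = tmp_path / "d.sky"
        p.write_text("<doc><settings/></doc>")
        with pytest.warns(UserWarning, match="no protein"):
            t = read_skyline(p)
        assert t.n_rows == 0


_cell = st.text(
    alphabet=st.sampled_from(list("abcXYZ019 ,;\"'")), max_size=8
).filter(lambda s: s == s.strip())
_header = st.text(alphabet=st.sampled_from(list("abcxyz")), min_size=1, max_size=6)


class TestWriteCsv:
    @given(headers=st.lists(_header, min_size=1, max_size=4, unique=True),
           n_rows=st.integers(0, 6), data=st.data())
    def test_write_read_round_trip(self, tmp_path_factory, headers, n_rows, data):
        cols = {h: data.draw(st.lists(_cell, min_size=n_rows, max_size=n_rows))
                for h in headers}
        t = make_table(cols)
        p = tmp_path_factory.mktemp("rt") / "t.csv"
        write_csv(t, p)
        if n_rows:
            back = read_table(p)
        else:
            with pytest.warns(UserWarning):
                back = read_table(p)
        assert back.headers == t.headers
        assert back.df.values.tolist() == t.df.values.tolist()

    def test_cell_with_comma_is_quoted(self, tmp_path):
        t = make_table({"a": ["x,y"], "b": ["1"]})
        p = tmp_path / "t.csv"
        write_csv(t, p)
        assert '"x,y"' in p.read_text()

    def test_empty_table_writes_header_only(self, tmp_path):
        t = make_table({"a": [], "b": []})
        p = tmp_path / "t.csv"
        write_csv(t, p)
        assert p.read_text() == "a,b\n"
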