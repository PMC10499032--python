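import random

import pytest
from hypothesis import given, strategies as st

from matrisomekit import annotate_gocc, load_gocc_map, matriannotate
from matrisomekit.annotate import (
    CATEGORY_COLUMN,
    DIVISION_COLUMN,
    GOCC_COLUMN,
)
from matrisomekit.errors import ParameterError
from matrisomekit.identifiers import normalize_identifier, normalize_token
from matrisomekit.reference import CORE, NON_MATRISOME, category_division_map
from conftest import make_table


def brute_force_classify(raw_id, ref):
    """O(keys x entries x aliases) oracle for one identifier cell."""
    for key in normalize_identifier(raw_id):
        for entry in ref.entries:
            for _, alias in entry.aliases():
                if normalize_token(alias) == key:
                    return entry.division, entry.category
    return NON_MATRISOME, NON_MATRISOME


class TestMatriannotate:
    def test_basic_classification(self, small_table, human_ref):
        ann = matriannotate(small_table, "ID", "human", human_ref)
        rows = dict(zip(ann.df["ID"], zip(ann.divisions, ann.categories)))
        assert rows["COL1A1"] == (CORE, "Collagens")
        assert rows["ZZZ999"] == (NON_MATRISOME, NON_MATRISOME)
        assert rows["tgfb1"] == ("Matrisome-associated", "Secreted Factors")

    def test_multi_id_cell_resolved_by_leading_identifier(self, small_table, human_ref):
        ann = matriannotate(small_table, "ID", "human", human_ref)
        i = ann.df["ID"].tolist().index("P02452-2;JUNK1")
        assert ann.categories.iloc[i] == "Collagens"
        rec = ann.match_log[i]
        assert rec.alias == "P02452" and rec.namespace == "uniprot"
        assert rec.gene_symbol == "COL1A1"

    def test_output_sorted_with_annotation_columns_first(self, human_ref):
        t = make_table({"Gene": ["mmp2", "ACAN", "zzz", "Bgn"],
                        "n": ["1", "2", "3", "4"],
                        "extra": ["w", "x", "y", "z"]})
        ann = matriannotate(t, "Gene", "human", human_ref)
        assert ann.table.headers == ["Gene", DIVISION_COLUMN, CATEGORY_COLUMN, "n", "extra"]
        assert ann.df["Gene"].tolist() == ["ACAN", "Bgn", "mmp2", "zzz"]
        # original columns travel with their rows
        assert ann.df["n"].tolist() == ["2", "4", "1", "3"]

    def test_shuffled_input_matches_brute_force(self, human_ref):
        rng = random.Random(7)
        aliases = [a for e in human_ref.entries for _, a in e.aliases()]
        ids = rng.sample(aliases, 4) + [f"DEC{i}" for i in range(6)]
        rng.shuffle(ids)
        t = make_table({"ID": ids, "v": [str(i) for i in range(len(ids))]})
        ann = matriannotate(t, "ID", "human", human_ref)
        assert ann.df["ID"].tolist() == sorted(ids, key=str.upper)
        for raw, div, cat in zip(ann.df["ID"], ann.divisions, ann.categories):
            assert (div, cat) == brute_force_classify(raw, human_ref)

    def test_division_category_always_consistent(self, human_ref):
        t = make_table({"ID": ["FN1", "nope", "MMP2", "P16112"]})
        ann = matriannotate(t, "ID", "human", human_ref)
        mapping = category_division_map()
        for div, cat in zip(ann.divisions, ann.categories):
            if cat == NON_MATRISOME:
                assert div == NON_MATRISOME
            else:
                assert mapping[cat] == div

    @given(ids=st.lists(st.sampled_from(
        ["COL1A1", "p02452", "FN1;X1", "junk", "", "7422", "Acan "]), max_size=12))
    def test_row_conservation(self, ids, human_ref):
        t = make_table({"ID": ids, "v": ["1"] * len(ids)})
        if ids and not any(normalize_identifier(i) and human_ref.lookup(
                normalize_identifier(i)[0]) for i in ids):
            with pytest.warns(UserWarning, match="no identifiers mapped"):
                ann = matriannotate(t, "ID", "human", human_ref)
        else:
            ann = matriannotate(t, "ID", "human", human_ref)
        assert ann.table.n_rows == len(ids)
        assert len(ann.match_log) == len(ids)

    def test_permutation_invariance(self, human_ref):
        ids = ["FN1", "zz1", "MMP2", "col3a1", "P01033", "aa2"]
        t1 = make_table({"ID": ids})
        t2 = make_table({"ID": list(reversed(ids))})
        a1 = matriannotate(t1, "ID", "human", human_ref)
        a2 = matriannotate(t2, "ID", "human", human_ref)
        assert a1.df.equals(a2.df)

    def test_idempotence_on_own_id_column(self, human_ref):
        t = make_table({"ID": ["COL1A1", "junk", "VEGFA"]})
        first = matriannotate(t, "ID", "human", human_ref)
        again = matriannotate(make_table({"ID": first.df["ID"].tolist()}),
                              "ID", "human", human_ref)
        assert first.divisions.tolist() == again.divisions.tolist()
        assert first.categories.tolist() == again.categories.tolist()

    def test_every_alias_recovered_in_any_case(self, all_refs):
        for species, ref in all_refs.items():
            for entry in ref.entries:
                for _, alias in entry.aliases():
                    for variant in (alias.upper(), alias.lower(), alias.title()):
                        t = make_table({"ID": [variant]})
                        ann = matriannotate(t, "ID", species, ref)
                        assert ann.divisions.iloc[0] == entry.division, (species, variant)
                        assert ann.categories.iloc[0] == entry.category

    def test_blank_identifier_kept_as_non_matrisome(self, human_ref):
        t = make_table({"ID": ["", "FN1"], "v": ["9", "8"]})
        ann = matriannotate(t, "ID", "human", human_ref)
        assert ann.table.n_rows == 2
        assert ann.divisions.iloc[0] == NON_MATRISOME  # blank sorts first

    def test_unknown_id_column_raises(self, small_table, human_ref):
        with pytest.raises(ParameterError, match="id_column"):
            matriannotate(small_table, "missing", "human", human_ref)

    def test_species_reference_mismatch_raises(self, small_table, human_ref):
        with pytest.raises(ParameterError, match="species"):
            matriannotate(small_table, "ID", "mouse", human_ref)

    def test_no_match_emits_review_warning(self, human_ref):
        t = make_table({"ID": ["nope1", "nope2"]})
        with pytest.warns(UserWarning, match="review input"):
            matriannotate(t, "ID", "human", human_ref)


class TestGoCc:
    def test_bundled_map_lookup_and_join(self):
        go = load_gocc_map("test-human-gocc")
        assert annotate_gocc(["ALB"], go) == ["extracellular region;blood microparticle"]
        assert annotate_gocc(["unmapped"], go) == [""]
        assert annotate_gocc(["alb"], go) == annotate_gocc(["ALB"], go)

    def test_gocc_column_added_fourth(self, human_ref):
        go = load_gocc_map("test-human-gocc")
        t = make_table({"ID": ["COL1A1", "ALB"], "v": ["1", "2"]})
        ann = matriannotate(t, "ID", "human", human_ref, go_map=go)
        assert ann.table.headers[:4] == ["ID", DIVISION_COLUMN, CATEGORY_COLUMN, GOCC_COLUMN]
        by_id = dict(zip(ann.df["ID"], ann.df[GOCC_COLUMN]))
        # matrisome rows are annotated too, not only non-matrisome ones
        assert "collagen" in by_id["COL1A1"]
        assert by_id["ALB"] == "extracellular region;blood microparticle"

    def test_isoform_id_finds_base_accession_terms(self):
        go = load_gocc_map("test-human-gocc")
        assert annotate_gocc(["P02452-2"], go) == ["collagen-containing extracellular matrix"]
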