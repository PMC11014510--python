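"""Loss-summary parsing, binary coding, matrix assembly and serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dolloloss.toga_io import (
    Blacklist,
    PresenceMatrix,
    TogaParseError,
    TogaRecord,
    assemble_matrix,
    code_presence,
    default_blacklist,
    filter_blacklist,
    parse_toga_summary,
    read_matrix,
    write_matrix,
)


class TestParse:
    def test_single_gene_line(self):
        (rec,) = parse_toga_summary("GENE\tMLKL\tL")
        assert rec == TogaRecord("GENE", "MLKL", "L")

    def test_empty_stream(self):
        assert parse_toga_summary("") == []

    def test_mixed_entry_classes(self):
        recs = parse_toga_summary(
            "GENE\tRIPK3\tL\nTRANSCRIPT\tENST0001\tI\nGENE\tAIM2\tUL\n"
        )
        assert len(recs) == 3
        assert sum(r.is_gene for r in recs) == 2

    def test_malformed_line_names_line_number(self):
        with pytest.raises(TogaParseError, match="line 2"):
            parse_toga_summary("GENE\tA\tL\nGENE\tB\n")

    def test_unknown_entry_class_rejected(self):
        with pytest.raises(TogaParseError, match="line 1"):
            parse_toga_summary("LOCUS\tA\tL")


class TestCoding:
    def test_default_loss_statuses(self):
        states = code_presence(
            [TogaRecord("GENE", "RIPK3", "L"), TogaRecord("GENE", "TP53", "I")]
        )
        assert states == {"RIPK3": 0, "TP53": 1}

    def test_configurable_loss_set(self):
        states = code_presence(
            [TogaRecord("GENE", "X", "UL")], loss_statuses={"L", "UL"}
        )
        assert states == {"X": 0}

    def test_non_gene_records_ignored(self):
        states = code_presence([TogaRecord("TRANSCRIPT", "T1", "L")])
        assert states == {}

    def test_conflicting_duplicates_code_lost_with_warning(self):
        records = [TogaRecord("GENE", "X", "I"), TogaRecord("GENE", "X", "L"),
                   TogaRecord("GENE", "Y", "I"), TogaRecord("GENE", "Y", "I")]
        with pytest.warns(UserWarning, match="conflicting"):
            states = code_presence(records)
        assert states == {"X": 0, "Y": 1}
        # order of the duplicate rows must not matter
        with pytest.warns(UserWarning):
            flipped = code_presence(records[::-1])
        assert flipped == states


class TestAssemble:
    def test_identity_assembly(self):
        m = assemble_matrix({"s1": {"A": 1, "B": 0}, "s2": {"A": 1, "B": 1}})
        assert m.species == ["s1", "s2"]
        assert m.genes == ["A", "B"]
        assert m.states.tolist() == [[1, 0], [1, 1]]

    def test_union_fills_with_present(self):
        m = assemble_matrix({"s1": {"A": 1, "C": 0}, "s2": {"A": 0}})
        assert m.genes == ["A", "C"]
        assert m.character("C") == {"s1": 0, "s2": 1}

    def test_intersection_drops_private_genes(self):
        m = assemble_matrix(
            {"s1": {"A": 1, "C": 0}, "s2": {"A": 0}}, universe_policy="intersection"
        )
        assert m.genes == ["A"]

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="two species"):
            assemble_matrix({"s1": {"A": 1}})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_matrix(
                {"s1": {"A": 1}, "s2": {"B": 0}}, universe_policy="intersection"
            )


class TestBlacklist:
    def test_empty_blacklist_is_noop_and_filter_idempotent(self):
        m = PresenceMatrix(["s1", "s2"], ["KRT5", "MLKL"], np.array([[1, 0], [1, 1]]))
        bl = Blacklist(("NOSUCHGENE",))
        assert filter_blacklist(m, bl) == m
        once = filter_blacklist(m, Blacklist(("KRT*",)))
        twice = filter_blacklist(once, Blacklist(("KRT*",)))
        assert once.genes == ["MLKL"] and once == twice

    def test_all_genes_blacklisted_warns_and_yields_zero_genes(self):
        m = PresenceMatrix(["s1", "s2"], ["KRT5"], np.array([[1], [0]]))
        with pytest.warns(UserWarning, match="every gene"):
            out = filter_blacklist(m, Blacklist(("KRT*",)))
        assert out.genes == []

    def test_default_blacklist_patterns(self):
        bl = default_blacklist()
        for gene in ("C1orf112", "DEFB1", "KRTAP4-1", "SLC22A12", "ZNF385C"):
            assert bl.matches(gene), gene
        for gene in ("MLKL", "RIPK3", "NLRC4"):
            assert not bl.matches(gene), gene


class TestSerialisation:
    @pytest.fixture
    def matrix(self, rng):
        from conftest import random_matrix

        return random_matrix(rng, ["sp_one", "sp_two", "sp_three"], 8)

    def test_phylip_header_and_padding(self, matrix):
        text = write_matrix(matrix, "phylip-discrete")
        lines = text.splitlines()
        assert lines[0] == "3 8"
        assert lines[1].startswith("sp_one".ljust(10))

    def test_phylip_truncation_collision_rejected(self):
        m = PresenceMatrix(
            ["longspeciesname_a", "longspeciesname_b"], ["g"], np.ones((2, 1))
        )
        with pytest.raises(ValueError, match="collide"):
            write_matrix(m, "phylip-discrete")

    @pytest.mark.parametrize("fmt", ["tsv", "nexus"])
    def test_roundtrip_preserves_everything(self, matrix, fmt):
        again = read_matrix(write_matrix(matrix, fmt), fmt)
        assert again.species == matrix.species
        assert again.genes == matrix.genes
        assert again == matrix

    def test_nexus_declares_standard_binary_data(self, matrix):
        text = write_matrix(matrix, "nexus")
        assert 'SYMBOLS="01"' in text and "DATATYPE=STANDARD" in text


@settings(max_examples=30, derandomize=True)
@given(
    statuses=st.lists(
        st.sampled_from(["L", "I", "UL", "PI", "M"]), min_size=1, max_size=6
    )
)
def test_coding_is_total_and_any_loss_wins(statuses):
    """Every GENE record codes to exactly one of {0,1}; any 'L' forces 0."""
    import warnings

    records = [TogaRecord("GENE", "G1", s) for s in statuses]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        states = code_presence(records)
    assert set(states) == {"G1"}
    assert states["G1"] == (0 if "L" in statuses else 1)
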