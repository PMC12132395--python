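"""Format layer: parsing fidelity, round trips, and strict error contracts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthocensus.errors import ConfigError, ConsistencyError, FormatError
from orthocensus.formats import (
    FastaRecord,
    GeneClusterMap,
    IntervalFeature,
    OrthogroupTable,
    SpeciesGroupConfig,
    load_group_config,
    read_cluster_map,
    read_fasta,
    read_gff3,
    read_orthogroup_table,
    write_cluster_map,
    write_fasta,
    write_gff3,
    write_group_config,
    write_orthogroup_table,
)

IDENT = st.text(alphabet="abcdefgXYZ0123456789_.-", min_size=1, max_size=8)


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------


def test_orthogroup_table_empty(tmp_path):
    f = tmp_path / "og.tsv"
    f.write_text("Orthogroup\tA\tB\n")
    table = read_orthogroup_table(f)
    assert table.proteomes == ["A", "B"]
    assert table.n_orthogroups == 0


def test_orthogroup_row_parsing_preserves_order_and_empties(tmp_path):
    f = tmp_path / "og.tsv"
    f.write_text("Orthogroup\tA\tB\nOG1\tp1, p2\t\n")
    table = read_orthogroup_table(f)
    # hand-tokenized: split on tab, then on ", "
    assert table.members("OG1", "A") == ["p1", "p2"]
    assert table.members("OG1", "B") == []


def test_orthogroup_tolerates_bare_commas(tmp_path):
    f = tmp_path / "og.tsv"
    f.write_text("Orthogroup\tA\nOG1\tp1,p2,  p3\n")
    assert read_orthogroup_table(f).members("OG1", "A") == ["p1", "p2", "p3"]


def test_orthogroup_roundtrip_byte_identical(tmp_path):
    f = tmp_path / "og.tsv"
    content = "Orthogroup\tA\tB\nOG1\tp1, p2\t\nOG2\t\tq1\n"
    f.write_text(content)
    out = tmp_path / "out.tsv"
    write_orthogroup_table(read_orthogroup_table(f), out)
    assert out.read_text() == content


def test_single_protein_cell_has_no_separator(tmp_path):
    table = OrthogroupTable(["A"], {"OG1": {"A": ["p1"]}})
    out = tmp_path / "out.tsv"
    write_orthogroup_table(table, out)
    data_line = out.read_text().splitlines()[1]
    assert data_line == "OG1\tp1"
    assert "," not in data_line


@pytest.mark.parametrize(
    "body, match",
    [
        ("OG1\tp1\n", "line 2"),  # ragged row
        ("OG1\tp1\tq\nOG1\tp2\tq2\n", "duplicate orthogroup"),
        ("OG1\tp1, p1\tq\n", "duplicate protein"),
    ],
)
def test_orthogroup_format_errors(tmp_path, body, match):
    f = tmp_path / "og.tsv"
    f.write_text("Orthogroup\tA\tB\n" + body)
    with pytest.raises(FormatError, match=match):
        read_orthogroup_table(f)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    proteomes=st.lists(IDENT, min_size=1, max_size=5, unique=True),
    og_ids=st.lists(IDENT, min_size=0, max_size=6, unique=True),
    data=st.data(),
)
def test_orthogroup_roundtrip_property(tmp_path_factory, proteomes, og_ids, data):
    """write∘read is the identity on random valid tables, order included."""
    orthogroups = {
        og: {
            p: data.draw(
                st.lists(IDENT, min_size=0, max_size=4, unique=True),
                label=f"{og}/{p}",
            )
            for p in proteomes
        }
        for og in og_ids
    }
    table = OrthogroupTable(list(proteomes), orthogroups)
    d = tmp_path_factory.mktemp("rt")
    write_orthogroup_table(table, d / "t.tsv")
    back = read_orthogroup_table(d / "t.tsv")
    assert back.proteomes == table.proteomes
    assert back.orthogroups == table.orthogroups


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_fasta_header_split_and_description(tmp_path):
    f = tmp_path / "a.fa"
    f.write_text(">p1 desc here\nMKV\n")
    (rec,) = read_fasta(f)
    assert (rec.id, rec.description, rec.sequence) == ("p1", "desc here", "MKV")


def test_fasta_multiline_concatenation_and_empty(tmp_path):
    f = tmp_path / "a.fa"
    f.write_text(">p2\nMK\nVA\n")
    assert read_fasta(f)[0].sequence == "MKVA"
    empty = tmp_path / "e.fa"
    empty.write_text("")
    assert read_fasta(empty) == []


def test_fasta_sequence_before_header_is_error(tmp_path):
    f = tmp_path / "bad.fa"
    f.write_text("MKV\n>p1\nMK\n")
    with pytest.raises(FormatError, match="before any"):
        read_fasta(f)


def test_fasta_roundtrip(tmp_path):
    records = [
        FastaRecord("p1", "some description", "MKVLA" * 30),
        FastaRecord("p2", "", "MK"),
    ]
    write_fasta(records, tmp_path / "rt.fa")
    assert read_fasta(tmp_path / "rt.fa") == records


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _feature(**kw):
    base = dict(
        seqid="s1",
        source="test",
        feature_type="mRNA",
        start=1,
        end=10,
        score=None,
        strand="+",
        phase=".",
        attributes={"ID": "t1", "cluster": "c1"},
    )
    base.update(kw)
    return IntervalFeature(**base)


def test_gff3_attribute_parsing(tmp_path):
    f = tmp_path / "a.gff3"
    f.write_text("##gff-version 3\ns1\tsrc\tmRNA\t5\t8\t.\t+\t.\tID=t1;cluster=c1\n")
    (feat,) = read_gff3(f)
    assert feat.attributes == {"ID": "t1", "cluster": "c1"}
    assert (feat.start, feat.end) == (5, 8)


def test_gff3_reserved_characters_roundtrip(tmp_path):
    feat = _feature(attributes={"ID": "t1", "note": "a;b=c,d&e%f\tg"})
    write_gff3([feat], tmp_path / "x.gff3")
    (back,) = read_gff3(tmp_path / "x.gff3")
    assert back.attributes == feat.attributes


def test_gff3_empty_writes_header_only(tmp_path):
    write_gff3([], tmp_path / "x.gff3")
    assert (tmp_path / "x.gff3").read_text() == "##gff-version 3\n"


def test_gff3_length_one_feature_start_equals_end():
    assert _feature(start=7, end=7).start == 7


@pytest.mark.parametrize(
    "line, match",
    [
        ("s1\tsrc\tmRNA\t9\t5\t.\t+\t.\tID=t1", "end 5 < start 9"),
        ("s1\tsrc\tmRNA\tx\t5\t.\t+\t.\tID=t1", "non-integer"),
        ("s1\tsrc\tmRNA\t1\t5\t.\t+\t.", "9 columns"),
    ],
)
def test_gff3_format_errors(tmp_path, line, match):
    f = tmp_path / "bad.gff3"
    f.write_text(line + "\n")
    with pytest.raises(FormatError, match=match):
        read_gff3(f)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    values=st.lists(
        st.text(
            alphabet=st.characters(
                codec="ascii", min_codepoint=32, max_codepoint=126
            ).map(str)
            | st.sampled_from(list(";=&,%\t")),
            max_size=12,
        ),
        min_size=1,
        max_size=4,
    ),
    start=st.integers(min_value=1, max_value=10**6),
    length=st.integers(min_value=0, max_value=500),
)
def test_gff3_roundtrip_property(tmp_path_factory, values, start, length):
    attrs = {f"k{i}": v for i, v in enumerate(values)}
    feat = _feature(start=start, end=start + length, attributes=attrs)
    d = tmp_path_factory.mktemp("gff")
    write_gff3([feat], d / "f.gff3")
    (back,) = read_gff3(d / "f.gff3")
    assert back == feat


# ---------------------------------------------------------------------------
# Cluster map & group config
# ---------------------------------------------------------------------------


def test_cluster_map_roundtrip_and_total_lookup(tmp_path):
    cmap = GeneClusterMap({"p1": ("A", "c1"), "p2": ("A", "c1")})
    write_cluster_map(cmap, tmp_path / "m.tsv")
    back = read_cluster_map(tmp_path / "m.tsv")
    assert back.entries == cmap.entries
    assert back.lookup("p1") == ("A", "c1")
    with pytest.raises(ConsistencyError, match="no gene-cluster mapping"):
        back.lookup("ghost")


def _config(**kw):
    base = dict(
        proteomes=("A1", "R", "M", "D"),
        focal_assemblies=frozenset({"A1"}),
        conspecific=frozenset({"A1", "R"}),
        ingroup=frozenset({"A1", "R", "M"}),
        required_species="D",
    )
    base.update(kw)
    return SpeciesGroupConfig(**base)


def test_group_config_valid_nesting_and_roundtrip(tmp_path):
    config = _config()
    assert config.reference_proteomes == {"R"}
    assert config.outgroup == {"D"}
    write_group_config(config, tmp_path / "g.cfg")
    assert load_group_config(tmp_path / "g.cfg") == config


def test_group_config_nesting_violation():
    with pytest.raises(ConfigError, match="A1"):
        _config(conspecific=frozenset({"R"}))


def test_group_config_required_species_inside_ingroup():
    with pytest.raises(ConfigError, match="outside"):
        _config(required_species="M")


def test_group_config_counting_unit_defaults_to_species(tmp_path):
    f = tmp_path / "g.cfg"
    f.write_text(
        "proteomes = A1, R, M, D\nfocal_assemblies = A1\n"
        "conspecific = A1, R\ningroup = A1, R, M\nrequired_species = D\n"
    )
    assert load_group_config(f).counting_unit == "species"
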